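"""Microstructure-derived fiber orientation distributions and field comparison.

A muFOD collects every stored orientation of every unmasked pixel in a
kernel or region of interest into a polar histogram of 20 bins of 9 deg
covering [0, 180), mirrored to [180, 360) (fiber orientations are
axial).  A periodic cubic spline through the bin mid-points gives the
continuous polar function used for display and for diffusion-signal
synthesis.  Two co-registered orientation fields are compared through
the circular half-turn distance of their dominant orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ValidationError
from .profile_analysis import OrientationField

__all__ = [
    "N_BINS",
    "BIN_WIDTH_DEG",
    "MuFOD",
    "DifferenceResult",
    "bin_midpoints",
    "compute_mufod",
    "mufod_grid",
    "spline_mufod",
    "angular_difference",
    "orientation_difference",
]

N_BINS = 20
BIN_WIDTH_DEG = 180.0 / N_BINS  # 9 deg


def bin_midpoints() -> np.ndarray:
    """Mid-points of the 20 half-turn bins: 4.5, 13.5, ..., 175.5 deg."""
    return (np.arange(N_BINS) + 0.5) * BIN_WIDTH_DEG


@dataclass
class MuFOD:
    """Polar histogram of fiber orientations over a region.

    ``counts[k]`` is the number of orientation entries falling in
    ``[9k, 9(k+1))`` degrees; the distribution is mirror-symmetric by
    construction (an orientation theta also represents theta + 180).
    """

    counts: np.ndarray
    bin_edges_deg: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_BINS,):
            raise ValidationError(f"counts must have {N_BINS} bins")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class DifferenceResult:
    """Pixel-wise angular difference between two orientation fields."""

    diff_map: np.ndarray
    hist_counts: np.ndarray
    hist_edges_deg: np.ndarray
    median_deg: float
    fwhm_deg: float
    n_pixels: int

    @property
    def empty(self) -> bool:
        return self.n_pixels == 0


def _region_mask(field: OrientationField, region) -> np.ndarray:
    if region is None:
        return np.ones(field.shape, dtype=bool)
    if isinstance(region, tuple):
        m = np.zeros(field.shape, dtype=bool)
        m[region] = True
        return m
    m = np.asarray(region, dtype=bool)
    if m.shape != field.shape:
        raise ValidationError("region mask shape must match the field")
    return m


def compute_mufod(field: OrientationField, region=None, label: str = "") -> MuFOD:
    """Histogram every orientation of every unmasked pixel in a region.

    ``region`` may be None (whole field), a boolean mask, or a tuple of
    slices (a kernel grid cell).  Each stored orientation contributes
    one count to its 9-deg bin; an empty region yields all-zero counts.
    """
    m = _region_mask(field, region) & field.mask
    thetas = field.orientations_deg[m]
    thetas = thetas[~np.isnan(thetas)]
    edges = np.arange(N_BINS + 1) * BIN_WIDTH_DEG
    counts, _ = np.histogram(thetas % 180.0, bins=edges)
    return MuFOD(counts=counts, bin_edges_deg=edges, label=label)


def mufod_grid(field: OrientationField, kernel_px: int) -> list[list[MuFOD]]:
    """muFODs for every cell of a non-overlapping kernel tiling."""
    k = int(kernel_px)
    if k < 1:
        raise ValidationError("kernel_px must be >= 1")
    h, w = field.shape
    grid = []
    for r0 in range(0, h, k):
        row = []
        for c0 in range(0, w, k):
            sl = (slice(r0, min(r0 + k, h)), slice(c0, min(c0 + k, w)))
            row.append(compute_mufod(field, sl, label=f"cell_{r0}_{c0}"))
        grid.append(row)
    return grid


def spline_mufod(
    mufod: MuFOD, grid_step_deg: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Periodic cubic spline through the bin mid-points.

    The spline has period 180 deg (axial symmetry) and is evaluated on a
    grid over [0, 360), mirroring the half-turn to the full circle; it
    interpolates the bin counts at the mid-points exactly.  All-zero
    counts yield the zero function.
    """
    phi = np.arange(0.0, 360.0, grid_step_deg)
    if mufod.total == 0:
        return phi, np.zeros_like(phi)
    x = bin_midpoints()
    y = mufod.counts.astype(np.float64)
    cs = CubicSpline(
        np.r_[x, x[0] + 180.0], np.r_[y, y[0]], bc_type="periodic"
    )
    values = cs((phi - x[0]) % 180.0 + x[0])
    return phi, values


def angular_difference(theta_a, theta_b) -> np.ndarray:
    """Circular distance on the half-circle: min(|d|, 180 - |d|), in [0, 90]."""
    d = np.abs(np.asarray(theta_a, float) - np.asarray(theta_b, float)) % 180.0
    return np.minimum(d, 180.0 - d)


def _fwhm_from_histogram(counts: np.ndarray, edges: np.ndarray) -> float:
    """Full width at half the modal height, linearly interpolated.

    Crossing positions are found between bin centers on each side of the
    global mode; a side that never drops below half clamps at the domain
    edge.
    """
    if counts.sum() == 0:
        return float("nan")
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = int(np.argmax(counts))
    half = counts[mode] / 2.0

    def cross(idx_range, left_side: bool) -> float:
        prev = mode
        for i in idx_range:
            if counts[i] < half:
                # linear interpolation between centers[i] and centers[prev]
                c0, c1 = counts[i], counts[prev]
                frac = (half - c0) / (c1 - c0)
                return centers[i] + frac * (centers[prev] - centers[i])
            prev = i
        return edges[0] if left_side else edges[-1]

    left = cross(range(mode - 1, -1, -1), True)
    right = cross(range(mode + 1, len(counts)), False)
    return float(right - left)


def orientation_difference(
    field_a: OrientationField,
    field_b: OrientationField,
    bin_deg: float = 0.3,
    mode: str = "dominant",
) -> DifferenceResult:
    """Angular difference map and histogram between co-registered fields.

    ``mode='dominant'`` compares the best-prominence population of each
    field; ``mode='matched'`` averages, over populations of A, the
    distance to the nearest population of B.  Pixels masked or empty in
    either field are excluded; the histogram uses ``bin_deg`` bins over
    [0, 90] and is summarized by its median and by the FWHM around the
    modal bin.
    """
    if field_a.shape != field_b.shape:
        raise ValidationError("fields must be co-registered with equal shapes")
    valid = (
        field_a.mask
        & field_b.mask
        & (field_a.n_populations > 0)
        & (field_b.n_populations > 0)
    )
    diff_map = np.full(field_a.shape, np.nan)
    if mode == "dominant":
        diff_map[valid] = angular_difference(
            field_a.orientations_deg[valid, 0], field_b.orientations_deg[valid, 0]
        )
    elif mode == "matched":
        oa = field_a.orientations_deg[valid]  # N x 3
        ob = field_b.orientations_deg[valid]
        d = angular_difference(oa[:, :, None], ob[:, None, :])  # N x 3 x 3
        d = np.where(np.isnan(d), np.inf, d)
        nearest = d.min(axis=2)
        nearest = np.where(np.isinf(nearest), np.nan, nearest)
        diff_map[valid] = np.nanmean(nearest, axis=1)
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    diffs = diff_map[valid]
    n_bins = int(round(90.0 / bin_deg))
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    counts, _ = np.histogram(diffs, bins=edges)
    if diffs.size:
        median = float(np.median(diffs))
        fwhm = _fwhm_from_histogram(counts, edges)
    else:
        median = float("nan")
        fwhm = float("nan")
    return DifferenceResult(
        diff_map=diff_map,
        hist_counts=counts,
        hist_edges_deg=edges,
        median_deg=median,
        fwhm_deg=fwhm,
        n_pixels=int(diffs.size),
    )
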