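"""Fiber orientation maps, vector overlays, and crossing statistics.

Orientations are rendered with a cyclic color wheel where hue = 2*theta,
so angles 0 and 180 deg share a color.  Crossing statistics come in two
flavors: *kernel-based* crossings (does a kernel of microscopic pixels
contain any pixel with >= 2 populations?) and *apparent* crossings (how
many populations does the analyzer find after the raw intensities are
block-averaged to a coarser resolution?).  The former measures presence
of microscopic crossings, the latter their detectability at that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from skimage.draw import line as draw_line

from .calibration_io import AngularStack
from .profile_analysis import OrientationField, ProfileParams, analyze_stack

__all__ = [
    "CrossingSummary",
    "orientation_color",
    "render_fom",
    "vector_overlay",
    "crossing_fraction",
    "apparent_crossing_map",
]


@dataclass
class CrossingSummary:
    """Crossing statistics over a non-overlapping kernel tiling.

    ``map`` holds, per kernel, the maximum population count among its
    unmasked pixels (0 when the kernel has none); fractions are computed
    over kernels containing at least one unmasked pixel.
    """

    kernel_px: int
    resolution_um: float
    fraction_ge2: float
    fraction_3: float
    map: np.ndarray
    n_kernels: int


def orientation_color(theta_deg: np.ndarray) -> np.ndarray:
    """RGB color(s) for orientation(s): hue = 2*theta on an HSV wheel."""
    theta = np.asarray(theta_deg, dtype=np.float64)
    hsv = np.stack(
        [((2.0 * theta) % 360.0) / 360.0, np.ones_like(theta), np.ones_like(theta)],
        axis=-1,
    )
    return hsv_to_rgb(hsv)


def render_fom(field: OrientationField) -> np.ndarray:
    """Render a fiber orientation map at 2x resolution (uint8 RGB).

    Each pixel becomes a 2x2 subpixel block: single-orientation pixels
    are a solid hue; multi-orientation pixels cycle their population
    colors (ordered by ascending theta) through the subpixels; masked or
    empty pixels are black.  Pure view — the field is not modified.
    """
    h, w = field.shape
    ori = field.orientations_deg
    npop = field.n_populations.astype(int)

    # sort orientations ascending per pixel, NaN last
    sorted_ori = np.sort(np.where(np.isnan(ori), np.inf, ori), axis=-1)
    out = np.zeros((2 * h, 2 * w, 3), dtype=np.uint8)
    subpixel = ((0, 0), (0, 1), (1, 0), (1, 1))
    valid = field.mask & (npop > 0)
    for k, (dr, dc) in enumerate(subpixel):
        slot = np.where(valid, k % np.maximum(npop, 1), 0)
        theta = np.take_along_axis(sorted_ori, slot[..., None], axis=-1)[..., 0]
        rgb = (orientation_color(np.where(valid, theta, 0.0)) * 255).astype(np.uint8)
        rgb[~valid] = 0
        out[dr::2, dc::2] = rgb
    return out


def _cluster_orientations(
    thetas: np.ndarray, gap_deg: float = 15.0, max_clusters: int = 3
) -> list[float]:
    """Cluster angles mod 180 by splitting sorted gaps larger than gap_deg.

    Returns the circular mean (mod 180) of up to ``max_clusters`` largest
    clusters, sorted by cluster size descending.
    """
    t = np.sort(np.asarray(thetas, float) % 180.0)
    if t.size == 0:
        return []
    gaps = np.diff(np.r_[t, t[0] + 180.0])
    cut = np.flatnonzero(gaps > gap_deg)
    if cut.size == 0:
        groups = [t]
    else:
        # rotate so the sequence starts right after the largest gap
        start = (cut[np.argmax(gaps[cut])] + 1) % t.size
        rolled = np.r_[t[start:], t[:start] + 180.0]
        rgaps = np.diff(rolled)
        splits = np.flatnonzero(rgaps > gap_deg) + 1
        groups = np.split(rolled, splits)
    means = []
    for g in sorted(groups, key=len, reverse=True)[:max_clusters]:
        ang = np.deg2rad(2.0 * g)
        m = np.rad2deg(np.arctan2(np.sin(ang).sum(), np.cos(ang).sum())) / 2.0
        means.append(float(m % 180.0))
    return means


def vector_overlay(field: OrientationField, overlay_kernel: int = 15) -> np.ndarray:
    """Draw one orientation line per distinct population of each n x n block.

    Block orientations are clustered (gap-based, mod 180); each cluster
    is drawn as a wheel-colored segment through the block center at the
    cluster's mean angle.  Returns a uint8 RGB image at field resolution.
    """
    n = int(overlay_kernel)
    if n < 1:
        raise ValueError("overlay_kernel must be >= 1")
    h, w = field.shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    half = max((n - 1) / 2.0 * 0.9, 0.5)
    valid = field.mask & (field.n_populations > 0)
    for r0 in range(0, h, n):
        for c0 in range(0, w, n):
            block = (slice(r0, min(r0 + n, h)), slice(c0, min(c0 + n, w)))
            sel = valid[block]
            thetas = field.orientations_deg[block][sel]
            thetas = thetas[~np.isnan(thetas)]
            if thetas.size == 0:
                continue
            rc = (r0 + min(n, h - r0) / 2.0, c0 + min(n, w - c0) / 2.0)
            for theta in _cluster_orientations(thetas):
                # +x is the column axis, theta counterclockwise, rows grow down
                dc = half * np.cos(np.deg2rad(theta))
                dr = -half * np.sin(np.deg2rad(theta))
                rr, cc = draw_line(
                    int(round(rc[0] - dr)), int(round(rc[1] - dc)),
                    int(round(rc[0] + dr)), int(round(rc[1] + dc)),
                )
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                out[rr[keep], cc[keep]] = (orientation_color(theta) * 255).astype(np.uint8)
    return out


def _tile_starts(extent: int, k: int) -> list[tuple[int, int]]:
    """Non-overlapping tiles anchored at 0; trailing partial tile kept if >= 50% inside."""
    starts = []
    for s in range(0, extent, k):
        size = min(k, extent - s)
        if size * 2 >= k:
            starts.append((s, s + size))
    return starts


def crossing_fraction(field: OrientationField, kernel_px: int) -> CrossingSummary:
    """Kernel-based crossing statistics at one resolution.

    Tiles the field with non-overlapping ``kernel_px`` kernels anchored
    at pixel (0, 0); each kernel's value is the maximum population count
    among its unmasked pixels.  ``fraction_ge2`` (``fraction_3``) is the
    fraction of populated kernels whose value is >= 2 (== 3).
    """
    k = int(kernel_px)
    if k < 1:
        raise ValueError("kernel_px must be >= 1")
    h, w = field.shape
    k = min(k, max(h, w))  # kernel larger than image -> single kernel
    rows = _tile_starts(h, k)
    cols = _tile_starts(w, k)
    cmap = np.zeros((len(rows), len(cols)), dtype=np.uint8)
    populated = np.zeros(cmap.shape, dtype=bool)
    for i, (r0, r1) in enumerate(rows):
        for j, (c0, c1) in enumerate(cols):
            m = field.mask[r0:r1, c0:c1]
            if not m.any():
                continue
            cmap[i, j] = field.n_populations[r0:r1, c0:c1][m].max()
            populated[i, j] = True
    n_kernels = int(populated.sum())
    if n_kernels:
        vals = cmap[populated]
        f2 = float(np.mean(vals >= 2))
        f3 = float(np.mean(vals == 3))
    else:
        f2 = f3 = 0.0
    return CrossingSummary(
        kernel_px=k,
        resolution_um=k * field.pixel_size_um,
        fraction_ge2=f2,
        fraction_3=f3,
        map=cmap,
        n_kernels=n_kernels,
    )


def apparent_crossing_map(
    stack: AngularStack, factor: int, params: ProfileParams | None = None
) -> OrientationField:
    """Orientations after intensity downsampling (apparent crossings).

    The raw stack is block-averaged by ``factor`` per angle (emulating
    larger detector pixels; trailing rows/columns that do not fill a
    block are dropped), then analyzed as usual.
    """
    f = int(factor)
    if f < 1:
        raise ValueError("factor must be >= 1")
    if f == 1:
        return analyze_stack(stack, params)
    h, w, a = stack.data.shape
    h2, w2 = h // f, w // f
    trimmed = stack.data[: h2 * f, : w2 * f]
    reduced = trimmed.reshape(h2, f, w2, f, a).mean(axis=(1, 3))
    small = AngularStack(
        data=reduced,
        angles=stack.angles.copy(),
        pixel_size_um=stack.pixel_size_um * f,
        meta={**stack.meta, "downsample_factor": f},
    )
    return analyze_stack(small, params)
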