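"""Per-pixel fiber orientations from azimuthal intensity profiles.

Spatially oriented fibers scatter light predominantly perpendicular to
their axis, so a pixel's intensity-vs-illumination-angle profile I(phi)
shows peak *pairs* roughly 180 deg apart; the circular midline of a pair,
reduced modulo 180 deg, is the in-plane fiber orientation theta.  Up to
three pairs (three fiber populations) are resolved per pixel.

The per-pixel pipeline is: optional Fourier low-pass filtering of the
periodic profile, circular peak detection with a relative prominence
threshold and sub-sample refinement, greedy 180-deg pairing, and midline
computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .calibration_io import AngularStack
from .errors import ValidationError

__all__ = [
    "ProfileParams",
    "PeakSet",
    "OrientationField",
    "fourier_lowpass",
    "detect_peaks",
    "pair_peaks",
    "orientations_from_pairs",
    "analyze_stack",
]


@dataclass
class ProfileParams:
    """Tunable parameters of the profile analysis.

    fourier_cutoff_fraction / fourier_window_width
        Low-pass cutoff as a fraction of the Nyquist index and the
        relative width of the smooth roll-off around it.
    prominence_fraction
        Minimum peak prominence as a fraction of the profile's range.
    pairing_tolerance_deg
        Two peaks form a pair when their circular separation is within
        180 deg +/- this tolerance.
    max_populations
        Maximum number of peak pairs (fiber populations) kept per pixel.
    background_quantile
        If > 0, pixels whose mean scattering is below this quantile of
        the average map are masked before analysis.
    fourier_filter
        True/False to force filtering on/off; None selects it by angular
        sampling (profiles sampled finer than 15 deg are filtered).
    """

    fourier_cutoff_fraction: float = 0.40
    fourier_window_width: float = 0.225
    prominence_fraction: float = 0.08
    pairing_tolerance_deg: float = 35.0
    max_populations: int = 3
    background_quantile: float = 0.0
    fourier_filter: bool | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fourier_cutoff_fraction <= 1:
            raise ValidationError("fourier_cutoff_fraction must be in (0, 1]")
        if not 0 <= self.fourier_window_width < 1:
            raise ValidationError("fourier_window_width must be in [0, 1)")
        if not 0 < self.pairing_tolerance_deg < 90:
            raise ValidationError("pairing_tolerance_deg must be in (0, 90)")
        if self.max_populations not in (1, 2, 3):
            raise ValidationError("max_populations must be 1, 2 or 3")


@dataclass
class PeakSet:
    """Sub-sample peak azimuths (degrees, ascending in [0, 360)) and prominences."""

    positions_deg: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return len(self.positions_deg)


@dataclass
class OrientationField:
    """Per-pixel in-plane fiber orientations.

    ``orientations_deg`` is H x W x 3 with angles in [0, 180) ordered by
    decreasing pair prominence; unused slots are NaN.  ``n_populations``
    counts the stored orientations per pixel; masked pixels carry 0.
    """

    orientations_deg: np.ndarray
    n_populations: np.ndarray
    average_map: np.ndarray
    mask: np.ndarray
    pixel_size_um: float = 1.0
    params: ProfileParams | None = None
    prominences: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.n_populations.shape


def _filter_response(n: int, cutoff: float, window: float) -> np.ndarray:
    """Amplitude response over rFFT harmonic indices 0..n//2."""
    k = np.arange(n // 2 + 1, dtype=np.float64)
    k_nyq = n / 2.0
    kc = cutoff * k_nyq
    w = window * k_nyq
    h = np.ones_like(k)
    if w > 0:
        lo, hi = kc - w / 2.0, kc + w / 2.0
        mid = (k > lo) & (k < hi)
        h[mid] = 0.5 * (1.0 + np.cos(np.pi * (k[mid] - lo) / w))
        h[k >= hi] = 0.0
    else:
        h[k > kc] = 0.0
    h[0] = 1.0  # mean preserved exactly
    return h


def fourier_lowpass(profile: Sequence[float], params: ProfileParams) -> np.ndarray:
    """Low-pass filter a periodic azimuthal profile in the Fourier domain.

    Harmonics above ``cutoff * Nyquist`` are zeroed with a raised-cosine
    roll-off of relative width ``fourier_window_width``; the DC term (the
    profile mean) passes untouched.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.size < 8:
        raise ValidationError("profile needs at least 8 samples")
    h = _filter_response(p.size, params.fourier_cutoff_fraction, params.fourier_window_width)
    return np.fft.irfft(np.fft.rfft(p) * h, n=p.size)


def detect_peaks(profile: Sequence[float], params: ProfileParams) -> PeakSet:
    """Find peaks of a periodic profile on the circular azimuth domain.

    Local maxima with prominence >= ``prominence_fraction * (max - min)``
    are kept; positions are refined to sub-sample precision as the
    intensity-weighted centroid of the peak lobe above its
    half-prominence level.  A flat profile yields no peaks.
    """
    p = np.asarray(profile, dtype=np.float64)
    a = p.size
    rng = float(p.max() - p.min())
    if rng == 0.0:
        return PeakSet(np.empty(0), np.empty(0))
    threshold = params.prominence_fraction * rng
    step = 360.0 / a

    tiled = np.tile(p, 3)
    idx, props = find_peaks(tiled, prominence=threshold)
    keep = (idx >= a) & (idx < 2 * a)
    idx = idx[keep]
    proms = props["prominences"][keep]

    positions = np.empty(idx.size)
    for j, (i, pr) in enumerate(zip(idx, proms)):
        positions[j] = _refine_position(tiled, int(i), float(pr), a, step)
    order = np.argsort(positions)
    return PeakSet(positions[order], proms[order])


def _refine_position(tiled: np.ndarray, i: int, prom: float, a: int, step: float) -> float:
    """Half-prominence centroid of the lobe around tiled-index ``i``.

    The lobe is the piecewise-linear interpolant of the samples above
    the half-prominence level, limited to the peak's own monotone
    support (the walk stops at the first valley so an overlapping
    neighbor lobe is not swallowed), extended to the fractional
    positions where it crosses the level; the centroid of the area
    between lobe and level is the refined peak azimuth.
    """
    level = tiled[i] - prom / 2.0
    lo = i
    while lo - 1 >= 0 and tiled[lo - 1] > level and tiled[lo - 1] <= tiled[lo]:
        lo -= 1
    hi = i
    while hi + 1 < tiled.size and tiled[hi + 1] > level and tiled[hi + 1] <= tiled[hi]:
        hi += 1
    if hi - lo + 1 >= a or lo == 0 or hi == tiled.size - 1:
        # lobe spans the whole circle; fall back to the sample position
        return (i - a) * step % 360.0

    xs_all = [(k - a) * step for k in range(lo, hi + 1)]
    hs_all = [tiled[k] - level for k in range(lo, hi + 1)]
    if tiled[lo - 1] <= level:
        # fractional left crossing between lo-1 and lo
        t = (level - tiled[lo - 1]) / (tiled[lo] - tiled[lo - 1])
        xs_all.insert(0, (lo - 1 - a + t) * step)
        hs_all.insert(0, 0.0)
    if tiled[hi + 1] <= level:
        t = (tiled[hi] - level) / (tiled[hi] - tiled[hi + 1])
        xs_all.append((hi - a + t) * step)
        hs_all.append(0.0)

    area = 0.0
    moment = 0.0
    for (x0, h0), (x1, h1) in zip(zip(xs_all, hs_all), zip(xs_all[1:], hs_all[1:])):
        d = x1 - x0
        area += (h0 + h1) / 2.0 * d
        moment += d * ((2.0 * h0 + h1) * x0 + (h0 + 2.0 * h1) * x1) / 6.0
    if area <= 0:
        return (i - a) * step % 360.0
    return (moment / area) % 360.0


def pair_peaks(
    peaks: PeakSet, params: ProfileParams
) -> list[tuple[float, float, float]]:
    """Greedily match peaks into ~180-deg-separated pairs.

    Candidate pairs are peaks whose circular separation lies within
    180 deg +/- ``pairing_tolerance_deg``.  Pairs are taken in order of
    decreasing summed prominence (ties broken by ascending positions),
    each peak used at most once, at most ``max_populations`` pairs.
    Returns ``(pos_a, pos_b, summed_prominence)`` triples.
    """
    pos = peaks.positions_deg
    prom = peaks.prominences
    n = len(pos)
    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            sep = (pos[j] - pos[i]) % 360.0
            if abs(sep - 180.0) <= params.pairing_tolerance_deg:
                candidates.append(
                    (-(prom[i] + prom[j]), min(pos[i], pos[j]), max(pos[i], pos[j]), i, j)
                )
    candidates.sort()
    used: set[int] = set()
    pairs: list[tuple[float, float, float]] = []
    for negp, _, _, i, j in candidates:
        if i in used or j in used:
            continue
        pairs.append((float(pos[i]), float(pos[j]), -negp))
        used.update((i, j))
        if len(pairs) == params.max_populations:
            break
    return pairs


def orientations_from_pairs(pairs: list[tuple[float, float, float]]) -> list[float]:
    """Circular midline of each peak pair, reduced to [0, 180).

    The two antipodal midpoints of a pair coincide modulo 180 deg, so the
    orientation is well defined even when the separation is not exactly
    180 deg.  Orientations are returned sorted by pair prominence
    (already the order produced by :func:`pair_peaks`).
    """
    thetas = []
    for a, b, _ in pairs:
        mid = a + ((b - a) % 360.0) / 2.0
        theta = mid % 180.0
        if theta >= 180.0:  # float edge
            theta = 0.0
        thetas.append(theta)
    return thetas


def _analyze_profile(p: np.ndarray, params: ProfileParams) -> tuple[list[float], list[float]]:
    peaks = detect_peaks(p, params)
    pairs = pair_peaks(peaks, params)
    return orientations_from_pairs(pairs), [pr for _, _, pr in pairs]


def analyze_stack(stack: AngularStack, params: ProfileParams | None = None) -> OrientationField:
    """Run the full per-pixel orientation pipeline on a calibrated stack.

    Profiles sampled finer than 15 deg are Fourier low-pass filtered
    first (coarser samplings carry too few harmonics to benefit); this
    automatic choice can be overridden via ``params.fourier_filter``.
    Pixels with zero mean intensity — and, when ``background_quantile``
    is set, pixels below that quantile of the average map — are masked
    and report zero populations.
    """
    params = params or ProfileParams()
    h, w, a = stack.data.shape
    data = stack.data

    do_filter = params.fourier_filter
    if do_filter is None:
        do_filter = stack.step_deg < 15.0 - 1e-9
    if do_filter:
        resp = _filter_response(a, params.fourier_cutoff_fraction, params.fourier_window_width)
        data = np.fft.irfft(np.fft.rfft(data, axis=-1) * resp, n=a, axis=-1)

    average_map = stack.data.mean(axis=-1)
    mask = average_map > 0
    if params.background_quantile > 0:
        mask &= average_map > np.quantile(average_map, params.background_quantile)

    orientations = np.full((h, w, 3), np.nan)
    prominences = np.full((h, w, 3), np.nan)
    n_pop = np.zeros((h, w), dtype=np.uint8)

    flat = data.reshape(-1, a)
    flat_mask = mask.ravel()
    flat_ori = orientations.reshape(-1, 3)
    flat_prom = prominences.reshape(-1, 3)
    flat_n = n_pop.ravel()
    for idx in np.flatnonzero(flat_mask):
        thetas, proms = _analyze_profile(flat[idx], params)
        k = len(thetas)
        if k:
            flat_ori[idx, :k] = thetas
            flat_prom[idx, :k] = proms
            flat_n[idx] = k

    return OrientationField(
        orientations_deg=orientations,
        n_populations=n_pop,
        average_map=average_map,
        mask=mask,
        pixel_size_um=stack.pixel_size_um,
        params=params,
        prominences=prominences,
    )
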