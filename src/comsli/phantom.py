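"""Synthetic scattering phantoms with known fiber fields.

A fiber population at in-plane angle theta scatters perpendicular to the
fiber axis, producing a pair of intensity lobes at theta +/- 90 deg in
the azimuthal profile.  The phantom emulates that signal structure with
wrapped-Gaussian lobes on top of a baseline, an optional separable
multiplicative illumination (spatial pattern x per-angle gain), and
additive Gaussian sensor noise clipped at zero.  The generator returns
both the measurement stack and the ground-truth orientation field, so
the whole pipeline can be validated without any measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .calibration_io import AngularStack
from .errors import ValidationError
from .profile_analysis import OrientationField

__all__ = [
    "Illumination",
    "Region",
    "PhantomSpec",
    "generate_phantom",
    "generate_diffuser",
    "single_fiber_spec",
    "interleaved_domains_spec",
    "random_regions_spec",
    "default_angles",
]


def default_angles(n: int = 24) -> np.ndarray:
    """Equally spaced azimuths 0, 360/n, ... covering the full circle."""
    return np.arange(n) * 360.0 / n


@dataclass
class Illumination:
    """Separable multiplicative illumination: spatial pattern x per-angle gain."""

    spatial: np.ndarray | None = None  # H x W, > 0
    per_angle_gain: np.ndarray | None = None  # length A, > 0

    def cube(self, shape: tuple[int, int], n_angles: int) -> np.ndarray:
        s = np.ones(shape) if self.spatial is None else np.asarray(self.spatial, float)
        g = (
            np.ones(n_angles)
            if self.per_angle_gain is None
            else np.asarray(self.per_angle_gain, float)
        )
        if s.shape != shape:
            raise ValidationError("illumination spatial pattern shape mismatch")
        if g.size != n_angles:
            raise ValidationError("illumination per-angle gain length mismatch")
        if np.any(s <= 0) or np.any(g <= 0):
            raise ValidationError("illumination must be strictly positive")
        return s[:, :, None] * g[None, None, :]


@dataclass
class Region:
    """A set of pixels sharing the same fiber populations.

    ``populations`` is a list of (theta_deg, amplitude) with theta in
    [0, 180); at most three populations per region.
    """

    mask: np.ndarray
    populations: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.populations) > 3:
            raise ValidationError("at most 3 fiber populations per region")
        for theta, amp in self.populations:
            if amp < 0:
                raise ValidationError("population amplitudes must be >= 0")
            if not 0 <= theta < 180:
                raise ValidationError("population angles must be in [0, 180)")


@dataclass
class PhantomSpec:
    """Generative description of a synthetic fiber scene."""

    shape: tuple[int, int] = (64, 64)
    angles: np.ndarray = dc_field(default_factory=default_angles)
    regions: list[Region] = dc_field(default_factory=list)
    peak_width_deg: float = 6.0
    baseline: float = 1.0
    noise_sigma: float = 0.0
    illumination: Illumination | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if not 0 < self.peak_width_deg < 45:
            raise ValidationError("peak_width_deg must be in (0, 45)")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.baseline < 0:
            raise ValidationError("baseline must be >= 0")
        for r in self.regions:
            if r.mask.shape != tuple(self.shape):
                raise ValidationError("region mask shape must match phantom shape")


def _wrapped_gaussian(delta_deg: np.ndarray, sigma_deg: float) -> np.ndarray:
    """Unit-height Gaussian lobe wrapped onto the circle."""
    out = np.zeros_like(delta_deg, dtype=np.float64)
    for m in (-2, -1, 0, 1, 2):
        out += np.exp(-((delta_deg + 360.0 * m) ** 2) / (2.0 * sigma_deg**2))
    return out


def _region_profile(
    populations: Sequence[tuple[float, float]], angles: np.ndarray, sigma: float
) -> np.ndarray:
    """Azimuthal signal of a population set: paired lobes at theta +/- 90."""
    prof = np.zeros_like(angles, dtype=np.float64)
    for theta, amp in populations:
        d1 = (angles - (theta + 90.0) + 180.0) % 360.0 - 180.0
        d2 = (angles - (theta - 90.0) + 180.0) % 360.0 - 180.0
        prof += amp * (_wrapped_gaussian(d1, sigma) + _wrapped_gaussian(d2, sigma))
    return prof


def generate_phantom(spec: PhantomSpec) -> tuple[AngularStack, OrientationField]:
    """Synthesize a measurement stack and its ground-truth orientations.

    Noise is drawn from the spec's seed after illumination scaling;
    negative intensities are clipped at zero (sensor floor).  Truth
    orientations are stored sorted by decreasing amplitude.
    """
    h, w = spec.shape
    a = spec.angles.size
    data = np.full((h, w, a), float(spec.baseline))

    truth_ori = np.full((h, w, 3), np.nan)
    truth_n = np.zeros((h, w), dtype=np.uint8)

    for region in spec.regions:
        prof = _region_profile(region.populations, spec.angles, spec.peak_width_deg)
        data[region.mask] += prof
        pops = sorted(region.populations, key=lambda p: -p[1])
        thetas = [t for t, amp in pops if amp > 0]
        k = len(thetas)
        if k:
            truth_ori[region.mask, :k] = thetas
        truth_n[region.mask] = k

    if spec.illumination is not None:
        data *= spec.illumination.cube((h, w), a)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
        np.clip(data, 0.0, None, out=data)

    stack = AngularStack(
        data=data,
        angles=spec.angles.copy(),
        pixel_size_um=1.0,
        meta={"phantom": True, "seed": spec.seed},
    )
    truth = OrientationField(
        orientations_deg=truth_ori,
        n_populations=truth_n,
        average_map=data.mean(axis=-1),
        mask=np.ones((h, w), dtype=bool),
        pixel_size_um=1.0,
    )
    return stack, truth


def generate_diffuser(spec: PhantomSpec) -> AngularStack:
    """Smooth per-angle illumination stack without fiber signal.

    Shares the spec's illumination term exactly, so flat-field
    correction with this diffuser undoes the phantom's illumination.
    """
    h, w = spec.shape
    a = spec.angles.size
    data = np.full((h, w, a), float(spec.baseline))
    if spec.illumination is not None:
        data *= spec.illumination.cube((h, w), a)
    return AngularStack(
        data=data,
        angles=spec.angles.copy(),
        pixel_size_um=1.0,
        meta={"diffuser": True},
    )


def single_fiber_spec(
    shape: tuple[int, int] = (32, 32),
    theta: float = 30.0,
    amplitude: float = 1.0,
    n_angles: int = 24,
    **kwargs,
) -> PhantomSpec:
    """Uniform scene with one fiber population everywhere."""
    mask = np.ones(shape, dtype=bool)
    return PhantomSpec(
        shape=shape,
        angles=default_angles(n_angles),
        regions=[Region(mask, [(theta, amplitude)])],
        **kwargs,
    )


def interleaved_domains_spec(
    shape: tuple[int, int] = (32, 32),
    thetas: tuple[float, float] = (0.0, 90.0),
    block: int = 1,
    amplitude: float = 1.0,
    n_angles: int = 24,
    **kwargs,
) -> PhantomSpec:
    """Checkerboard of two single-fiber domains with period ``block``.

    Every pixel holds one population, but block-averaging over both
    domains superposes the two peak pairs — the construction behind
    apparent crossings at reduced resolution.
    """
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h) // block, np.arange(w) // block, indexing="ij")
    checker = (rr + cc) % 2 == 0
    return PhantomSpec(
        shape=shape,
        angles=default_angles(n_angles),
        regions=[
            Region(checker, [(thetas[0], amplitude)]),
            Region(~checker, [(thetas[1], amplitude)]),
        ],
        **kwargs,
    )


def random_regions_spec(
    shape: tuple[int, int] = (64, 64),
    patch: int = 16,
    n_angles: int = 24,
    max_populations: int = 3,
    min_separation_deg: float = 30.0,
    amplitude: float = 1.0,
    seed: int = 0,
    **kwargs,
) -> PhantomSpec:
    """Grid of square patches, each with 1..max_populations random fibers.

    Population angles within a patch are drawn with pairwise circular
    separation (mod 180) of at least ``min_separation_deg``.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    regions: list[Region] = []
    for r0 in range(0, h, patch):
        for c0 in range(0, w, patch):
            mask = np.zeros(shape, dtype=bool)
            mask[r0 : r0 + patch, c0 : c0 + patch] = True
            k = int(rng.integers(1, max_populations + 1))
            thetas: list[float] = []
            attempts = 0
            while len(thetas) < k and attempts < 200:
                cand = float(rng.uniform(0.0, 180.0))
                d = [min(abs(cand - t), 180.0 - abs(cand - t)) for t in thetas]
                if not d or min(d) >= min_separation_deg:
                    thetas.append(cand)
                attempts += 1
            regions.append(Region(mask, [(t, amplitude) for t in thetas]))
    return PhantomSpec(
        shape=shape, angles=default_angles(n_angles), regions=regions, seed=seed, **kwargs
    )
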