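"""Azimuthal image stacks and diffuser-based flat-field correction.

A scattered-light measurement is a series of camera images of the same
scene, one per azimuthal illumination angle.  The series is held as an
:class:`AngularStack` (H x W x A float cube plus its angle list).  Uneven
illumination across the field of view is removed by dividing each tissue
image by a normalized, heavily blurred image of a diffuser plate acquired
at the same illumination angle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .errors import CalibrationError, FormatError, ValidationError

__all__ = [
    "AngularStack",
    "CalibrationField",
    "read_angular_stack",
    "write_angular_stack",
    "normalize_diffuser",
    "flat_field_correct",
    "save_calibration",
    "load_calibration",
]

_ANGLE_SPACING_TOL = 1e-6


@dataclass
class AngularStack:
    """Intensity cube ``data[H, W, A]`` with its azimuth list.

    Angles are in degrees, strictly increasing, equally spaced over the
    full circle (spacing ``360/A``).  Intensities are non-negative floats
    in arbitrary camera units.
    """

    data: np.ndarray
    angles: np.ndarray
    pixel_size_um: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"stack must be H x W x A, got shape {self.data.shape}")
        n = self.angles.size
        if n < 8:
            raise ValidationError(f"need at least 8 azimuth angles, got {n}")
        if self.data.shape[2] != n:
            raise ValidationError(
                f"{self.data.shape[2]} image pages but {n} angles"
            )
        if np.any(np.diff(self.angles) <= 0):
            raise ValidationError("angles must be strictly increasing")
        if self.angles[0] < 0 or self.angles[-1] >= 360:
            raise ValidationError("angles must lie in [0, 360)")
        step = 360.0 / n
        expected = self.angles[0] + step * np.arange(n)
        if np.max(np.abs(self.angles - expected)) > _ANGLE_SPACING_TOL:
            raise ValidationError(f"angles must be equally spaced by {step} deg")
        if np.any(self.data < 0):
            raise ValidationError("intensities must be non-negative")

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    @property
    def step_deg(self) -> float:
        return 360.0 / self.n_angles

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]


@dataclass
class CalibrationField:
    """Unitless flat-field divisors, one grid per illumination angle.

    The field is normalized so that the mean over angles of the per-angle
    maxima equals 1; dividing a measurement by it equalizes illumination
    while preserving the overall intensity scale.
    """

    normalized: np.ndarray
    angles: np.ndarray
    blur_radius_px: float

    def __post_init__(self) -> None:
        self.normalized = np.asarray(self.normalized, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if np.any(self.normalized <= 0):
            raise CalibrationError("calibration divisors must be positive")
        mean_max = float(np.mean(self.normalized.max(axis=(0, 1))))
        if abs(mean_max - 1.0) > 1e-6:
            raise CalibrationError(
                f"mean of per-angle maxima is {mean_max}, expected 1"
            )


def read_angular_stack(
    paths: Sequence[str | Path] | str | Path,
    angles: Sequence[float],
    pixel_size_um: float = 1.0,
) -> AngularStack:
    """Read a multi-page TIFF or a list of per-angle TIFFs into a stack.

    Pages are re-ordered so the returned angle list is ascending; the
    angle list passed in must correspond to the pages in file order.
    Intensities are promoted to float64; the original dtype is recorded
    in ``meta['source_dtype']``.
    """
    angles = np.asarray(angles, dtype=np.float64)
    if angles.size != np.unique(angles).size:
        raise ValidationError("duplicate angles in angle list")

    if isinstance(paths, (str, Path)):
        pages = tifffile.imread(paths)
        if pages.ndim == 2:
            pages = pages[None]
        sources = [str(paths)]
    else:
        imgs = []
        for p in paths:
            img = tifffile.imread(p)
            if img.ndim != 2:
                raise FormatError(f"{p}: expected a single 2-D page, got shape {img.shape}")
            imgs.append(img)
        shapes = {im.shape for im in imgs}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent image shapes across files: {shapes}")
        pages = np.stack(imgs, axis=0)
        sources = [str(p) for p in paths]

    if pages.shape[0] != angles.size:
        raise ValidationError(
            f"{pages.shape[0]} pages but {angles.size} angles supplied"
        )
    src_dtype = str(pages.dtype)
    order = np.argsort(angles)
    data = np.moveaxis(pages[order].astype(np.float64), 0, -1)
    return AngularStack(
        data=data,
        angles=angles[order],
        pixel_size_um=pixel_size_um,
        meta={"source_dtype": src_dtype, "sources": sources},
    )


def write_angular_stack(stack: AngularStack, path: str | Path) -> Path:
    """Write a stack as a 32-bit multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(stack.data, -1, 0).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "angles_deg": stack.angles.tolist(),
                "pixel_size_um": stack.pixel_size_um,
                "meta": {k: v for k, v in stack.meta.items() if _jsonable(v)},
            },
            indent=2,
        )
    )
    return path


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def normalize_diffuser(
    diffuser: AngularStack, blur_radius_px: float = 100.0
) -> CalibrationField:
    """Turn a diffuser-plate stack into a flat-field calibration.

    Each angle's image is blurred with a Gaussian of standard deviation
    ``blur_radius_px`` (reflect boundary) to homogenize plate defects,
    then all blurred images are divided by the average of their per-angle
    maxima.
    """
    blurred = np.empty_like(diffuser.data)
    for a in range(diffuser.n_angles):
        blurred[:, :, a] = gaussian_filter(
            diffuser.data[:, :, a], sigma=blur_radius_px, mode="reflect"
        )
    maxima = blurred.max(axis=(0, 1))
    mean_max = float(maxima.mean())
    if mean_max <= 0 or np.any(blurred <= 0):
        raise CalibrationError("diffuser must be strictly positive after blurring")
    return CalibrationField(
        normalized=blurred / mean_max,
        angles=diffuser.angles.copy(),
        blur_radius_px=blur_radius_px,
    )


def flat_field_correct(
    stack: AngularStack,
    cal: CalibrationField,
    eps_fraction: float = 1e-6,
) -> AngularStack:
    """Divide each tissue image by the normalized diffuser at the same angle.

    Pixels whose divisor is below ``eps_fraction`` of the calibration
    field's maximum are masked (set to 0, counted in
    ``meta['n_masked_low_cal']``) instead of amplified.
    """
    if stack.data.shape != cal.normalized.shape:
        raise ValidationError(
            f"stack shape {stack.data.shape} != calibration shape {cal.normalized.shape}"
        )
    if not np.allclose(stack.angles, cal.angles, atol=_ANGLE_SPACING_TOL):
        raise ValidationError("stack and calibration angle lists differ")
    eps = eps_fraction * cal.normalized.max()
    low = cal.normalized < eps
    divisor = np.where(low, 1.0, cal.normalized)
    out = np.where(low, 0.0, stack.data / divisor)
    meta = dict(stack.meta)
    meta["flat_field_corrected"] = True
    meta["n_masked_low_cal"] = int(low.sum())
    return AngularStack(
        data=out,
        angles=stack.angles.copy(),
        pixel_size_um=stack.pixel_size_um,
        meta=meta,
    )


def save_calibration(cal: CalibrationField, path: str | Path) -> Path:
    """Cache a calibration field as TIFF + JSON metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(cal.normalized, -1, 0).astype(np.float32))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(
            {"angles_deg": cal.angles.tolist(), "blur_radius_px": cal.blur_radius_px},
            indent=2,
        )
    )
    return path


def load_calibration(path: str | Path) -> CalibrationField:
    path = Path(path)
    pages = tifffile.imread(path).astype(np.float64)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return CalibrationField(
        normalized=np.moveaxis(pages, 0, -1),
        angles=np.asarray(meta["angles_deg"]),
        blur_radius_px=meta["blur_radius_px"],
    )
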