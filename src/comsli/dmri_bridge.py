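"""Artificial diffusion-MRI dataset derived from per-pixel muFODs.

Standard tractography pipelines consume diffusion-weighted volumes, so
the measured in-plane fiber orientations are re-expressed as a synthetic
63-volume dataset: 3 unweighted (b=0) volumes and 60 volumes at
b = 1 ms/um^2 split into three 20-direction sets.

* in-plane set: gradient azimuths at the 20 muFOD bin mid-points; the
  signal is exp(-n/scale) where n is the bin count, so directions rich
  in fibers attenuate most.
* perpendicular set: 20 directions in a plane containing the section
  normal; signal identically 1 (no axons out of plane), confining the
  reconstructed distribution to the section plane.
* tilted set: the in-plane azimuths rotated toward the normal (default
  20 deg); signal 1 - (1 - S_inplane)/5, i.e. the attenuation 20 deg
  off-axis is exactly 20% of the on-axis attenuation — a sharp fiber
  response with fast off-axis fall-off.

Downstream consumers (not implemented here) are the usual external
tools: response estimation (fa algorithm, l_max = 6), constrained
spherical deconvolution (csd, l_max = 6), and streamline generation
with a 2 mm minimum tract length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError
from .mufod_stats import N_BINS, bin_midpoints, mufod_grid
from .profile_analysis import OrientationField

__all__ = [
    "GradientTable",
    "ArtificialDWI",
    "build_gradient_table",
    "synthesize_dwi",
    "export_dwi",
    "load_dwi",
]

N_B0 = 3
N_VOLUMES = N_B0 + 3 * N_BINS  # 63


@dataclass
class GradientTable:
    """63-entry gradient scheme: 3 b=0 plus three 20-direction b=1 sets."""

    bvals: np.ndarray  # ms/um^2
    bvecs: np.ndarray  # 63 x 3, unit norm for b=1 entries
    set_labels: list[str]  # 'b0' | 'inplane' | 'perpendicular' | 'tilted'
    tilt_deg: float = 20.0

    def indices(self, label: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.set_labels) if l == label])


@dataclass
class ArtificialDWI:
    """Synthetic diffusion volumes (H x W x 1 x 63, unitless in (0, 1])."""

    volumes: np.ndarray
    gradient_table: GradientTable
    pixel_size_um: float
    attenuation_scale: float = 10.0


def build_gradient_table(
    section_normal=(0.0, 0.0, 1.0), tilt_deg: float = 20.0
) -> GradientTable:
    """Construct the 63-direction gradient scheme around a section normal.

    In-plane directions sit at the muFOD bin mid-point azimuths
    (4.5 + 9k deg) in the section plane; the perpendicular set spans the
    plane holding the normal and the in-plane x-axis at the same angular
    spacing; the tilted set rotates every in-plane direction ``tilt_deg``
    toward the normal.
    """
    n = np.asarray(section_normal, dtype=np.float64)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValidationError("section normal must be non-degenerate")
    n = n / norm

    # in-plane orthonormal basis (e1, e2)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, n)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    az = np.deg2rad(bin_midpoints())
    inplane = np.cos(az)[:, None] * e1 + np.sin(az)[:, None] * e2
    perpendicular = np.cos(az)[:, None] * e1 + np.sin(az)[:, None] * n
    t = np.deg2rad(tilt_deg)
    tilted = np.cos(t) * inplane + np.sin(t) * n

    bvecs = np.vstack([np.zeros((N_B0, 3)), inplane, perpendicular, tilted])
    bvals = np.r_[np.zeros(N_B0), np.ones(3 * N_BINS)]
    labels = (
        ["b0"] * N_B0
        + ["inplane"] * N_BINS
        + ["perpendicular"] * N_BINS
        + ["tilted"] * N_BINS
    )
    return GradientTable(bvals=bvals, bvecs=bvecs, set_labels=labels, tilt_deg=tilt_deg)


def synthesize_dwi(
    field: OrientationField,
    kernel_px: int = 1,
    scale: float = 10.0,
    gradient_table: GradientTable | None = None,
) -> ArtificialDWI:
    """Convert an orientation field into the artificial diffusion dataset.

    With ``kernel_px == 1`` each pixel's own populations form its muFOD;
    larger kernels tile the field and emit one voxel per kernel (pixel
    size scales accordingly).  Per voxel and in-plane direction k the
    signal is exp(-n_k/scale); b=0 and perpendicular volumes are 1;
    tilted volumes are 1 - (1 - S_inplane)/5.  Voxels without any
    orientation (masked or empty) carry all-1 signals.
    """
    if kernel_px < 1:
        raise ValidationError("kernel_px must be >= 1")
    gtab = gradient_table or build_gradient_table()

    if kernel_px == 1:
        h, w = field.shape
        counts = np.zeros((h, w, N_BINS))
        thetas = field.orientations_deg
        valid = field.mask[:, :, None] & ~np.isnan(thetas)
        bins = np.floor_divide(np.where(valid, thetas, 0.0) % 180.0, 180.0 / N_BINS)
        bins = np.minimum(bins.astype(int), N_BINS - 1)
        rr, cc, ss = np.nonzero(valid)
        np.add.at(counts, (rr, cc, bins[rr, cc, ss]), 1.0)
        out_px = field.pixel_size_um
    else:
        grid = mufod_grid(field, kernel_px)
        h, w = len(grid), len(grid[0])
        counts = np.zeros((h, w, N_BINS))
        for i, row in enumerate(grid):
            for j, m in enumerate(row):
                counts[i, j] = m.counts
        out_px = field.pixel_size_um * kernel_px

    s_inplane = np.exp(-counts / scale)
    s_tilted = 1.0 - (1.0 - s_inplane) / 5.0

    volumes = np.ones((counts.shape[0], counts.shape[1], 1, N_VOLUMES))
    volumes[:, :, 0, gtab.indices("inplane")] = s_inplane
    volumes[:, :, 0, gtab.indices("tilted")] = s_tilted
    return ArtificialDWI(
        volumes=volumes,
        gradient_table=gtab,
        pixel_size_um=out_px,
        attenuation_scale=scale,
    )


def export_dwi(
    dwi: ArtificialDWI, out_prefix: str | Path, slice_thickness_um: float | None = None
) -> dict[str, Path]:
    """Write NIfTI + FSL bval/bvec + JSON sidecar for tractography tools.

    The b-values are written in s/mm^2 (b = 1 ms/um^2 -> 1000), the
    convention of downstream tools; ms/um^2 units are recorded in the
    JSON sidecar.  The slice is a 1-voxel-thick 3-D volume whose header
    voxel size encodes the pixel size (and slice thickness) in mm.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    px_mm = dwi.pixel_size_um / 1000.0
    thick_mm = (slice_thickness_um or dwi.pixel_size_um) / 1000.0
    affine = np.diag([px_mm, px_mm, thick_mm, 1.0])
    img = nib.Nifti1Image(dwi.volumes.astype(np.float32), affine)
    img.header.set_zooms((px_mm, px_mm, thick_mm, 1.0))

    paths = {
        "nifti": prefix.with_suffix(".nii"),
        "bval": prefix.with_suffix(".bval"),
        "bvec": prefix.with_suffix(".bvec"),
        "json": prefix.with_suffix(".json"),
    }
    try:
        nib.save(img, paths["nifti"])
        bvals_smm2 = (dwi.gradient_table.bvals * 1000.0).astype(int)
        paths["bval"].write_text(" ".join(str(b) for b in bvals_smm2) + "\n")
        rows = dwi.gradient_table.bvecs.T  # 3 x 63, signs match NIfTI axes
        paths["bvec"].write_text(
            "\n".join(" ".join(f"{v:.10f}" for v in row) for row in rows) + "\n"
        )
        paths["json"].write_text(
            json.dumps(
                {
                    "bvalue_units": "ms/um^2 (written as s/mm^2 in .bval)",
                    "bvalues_ms_per_um2": dwi.gradient_table.bvals.tolist(),
                    "set_labels": dwi.gradient_table.set_labels,
                    "tilt_deg": dwi.gradient_table.tilt_deg,
                    "attenuation_scale": dwi.attenuation_scale,
                    "pixel_size_um": dwi.pixel_size_um,
                    "slice_thickness_um": slice_thickness_um or dwi.pixel_size_um,
                    "suggested_downstream": [
                        "dwi2response fa -lmax 6 dwi.nii response.txt",
                        "dwi2fod csd dwi.nii response.txt fod.nii -lmax 6",
                        "tckgen fod.nii tracts.tck -minlength 2",
                    ],
                },
                indent=2,
            )
        )
    except OSError as exc:
        raise OSError(f"failed writing artificial DWI to {prefix}: {exc}") from exc
    return paths


def load_dwi(out_prefix: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Round-trip reader: (volumes, bvals s/mm^2, bvecs 63 x 3)."""
    prefix = Path(out_prefix)
    img = nib.load(prefix.with_suffix(".nii"))
    volumes = np.asarray(img.dataobj)
    bvals = np.loadtxt(prefix.with_suffix(".bval"))
    bvecs = np.loadtxt(prefix.with_suffix(".bvec")).T
    return volumes, bvals, bvecs
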