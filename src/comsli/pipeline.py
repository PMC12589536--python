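"""End-to-end orchestration: calibrate -> analyze -> products -> muFOD -> DWI.

A run is described by a plain config mapping (usually loaded from YAML)
and produces a manifest JSON recording inputs, parameters, checksums and
the package version, so identical configs and seeds give identical
artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .calibration_io import (
    flat_field_correct,
    normalize_diffuser,
    read_angular_stack,
    save_calibration,
    write_angular_stack,
)
from .dmri_bridge import export_dwi, synthesize_dwi
from .errors import ValidationError
from .mufod_stats import bin_midpoints, compute_mufod, spline_mufod
from .orientation_products import crossing_fraction, render_fom, vector_overlay
from .phantom import (
    generate_diffuser,
    generate_phantom,
    interleaved_domains_spec,
    random_regions_spec,
    single_fiber_spec,
)
from .profile_analysis import OrientationField, ProfileParams, analyze_stack

__all__ = ["run_pipeline", "save_orientation_field", "sha256_of"]

_PHANTOM_BUILDERS = {
    "single_fiber": single_fiber_spec,
    "interleaved_domains": interleaved_domains_spec,
    "random_regions": random_regions_spec,
}


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def save_orientation_field(field: OrientationField, outdir: Path, prefix: str = "field"):
    """Serialize an orientation field as per-population TIFFs + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(field.orientations_deg.shape[-1]):
        p = outdir / f"{prefix}_theta_{k}.tif"
        tifffile.imwrite(p, field.orientations_deg[:, :, k].astype(np.float32))
        paths.append(p)
    p_n = outdir / f"{prefix}_npop.tif"
    tifffile.imwrite(p_n, field.n_populations.astype(np.uint8))
    p_avg = outdir / f"{prefix}_avg.tif"
    tifffile.imwrite(p_avg, field.average_map.astype(np.float32))
    sidecar = outdir / f"{prefix}_params.json"
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size_um": field.pixel_size_um,
                "params": asdict(field.params) if field.params else None,
            },
            indent=2,
        )
    )
    return paths + [p_n, p_avg, sidecar]


def _build_phantom_stack(cfg: dict):
    kind = cfg.get("kind", "single_fiber")
    if kind not in _PHANTOM_BUILDERS:
        raise ValidationError(f"unknown phantom kind {kind!r}")
    kwargs = {k: v for k, v in cfg.items() if k != "kind"}
    if "shape" in kwargs:
        kwargs["shape"] = tuple(kwargs["shape"])
    if "thetas" in kwargs:
        kwargs["thetas"] = tuple(kwargs["thetas"])
    spec = _PHANTOM_BUILDERS[kind](**kwargs)
    stack, truth = generate_phantom(spec)
    return spec, stack, truth


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the artifact manifest.

    Recognized config keys: ``phantom`` (generate inputs), ``input`` /
    ``angles`` / ``pixel_size_um`` (read a measured stack), ``calibrate``
    (bool; phantom runs synthesize their own diffuser, measured runs
    need ``diffuser`` paths), ``profile`` (ProfileParams fields),
    ``kernel_sizes``, ``overlay_kernel``, ``mufod_kernel``,
    ``dwi`` ({kernel_px, scale, tilt_deg}), ``seed``, ``outdir``.
    """
    outdir = Path(outdir or config.get("outdir", "comsli_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": _jsonable_config(config),
        "stages": [],
        "artifacts": {},
    }

    def record(stage: str, paths):
        manifest["stages"].append(stage)
        for p in paths:
            manifest["artifacts"][str(Path(p).relative_to(outdir))] = sha256_of(p)

    # --- input stage -----------------------------------------------------
    diffuser = None
    if "phantom" in config:
        pcfg = dict(config["phantom"])
        pcfg.setdefault("seed", config.get("seed", 0))
        spec, stack, truth = _build_phantom_stack(pcfg)
        p = write_angular_stack(stack, outdir / "phantom_stack.tif")
        record("phantom", [p, Path(str(p) + ".json")])
        if config.get("calibrate", False):
            diffuser = generate_diffuser(spec)
    elif "input" in config:
        if config.get("calibrate", False) and "diffuser" not in config:
            raise ValidationError("calibrate=true requires 'diffuser' input paths")
        stack = read_angular_stack(
            config["input"], config["angles"], config.get("pixel_size_um", 1.0)
        )
        if config.get("calibrate", False):
            diffuser = read_angular_stack(
                config["diffuser"], config["angles"], config.get("pixel_size_um", 1.0)
            )
    else:
        raise ValidationError("config needs either 'phantom' or 'input'")

    # --- calibration -----------------------------------------------------
    if diffuser is not None:
        cal = normalize_diffuser(
            diffuser, blur_radius_px=float(config.get("blur_radius_px", 100.0))
        )
        p = save_calibration(cal, outdir / "calibration.tif")
        record("calibrate", [p, Path(str(p) + ".json")])
        stack = flat_field_correct(stack, cal)

    # --- orientation analysis -------------------------------------------
    params = ProfileParams(**config.get("profile", {}))
    field = analyze_stack(stack, params)
    record("analyze", save_orientation_field(field, outdir))

    # --- maps ------------------------------------------------------------
    fom = render_fom(field)
    p_fom = outdir / "fom.png"
    _write_png(p_fom, fom)
    overlay = vector_overlay(field, int(config.get("overlay_kernel", 15)))
    p_ov = outdir / "vector_overlay.png"
    _write_png(p_ov, overlay)
    record("maps", [p_fom, p_ov])

    # --- crossing statistics ---------------------------------------------
    kernel_sizes = config.get("kernel_sizes", [1, 7, 14, 71])
    rows = []
    for k in kernel_sizes:
        cs = crossing_fraction(field, int(k))
        rows.append(
            {
                "kernel_px": cs.kernel_px,
                "resolution_um": cs.resolution_um,
                "fraction_ge2": cs.fraction_ge2,
                "fraction_3": cs.fraction_3,
                "n_kernels": cs.n_kernels,
            }
        )
    p_cross = outdir / "crossings.csv"
    pd.DataFrame(rows).to_csv(p_cross, index=False)
    record("crossings", [p_cross])

    # --- muFOD -----------------------------------------------------------
    mufod = compute_mufod(field, label="whole_field")
    phi, spline = spline_mufod(mufod)
    p_mufod = outdir / "mufod.csv"
    pd.DataFrame(
        {"bin_midpoint_deg": bin_midpoints(), "count": mufod.counts}
    ).to_csv(p_mufod, index=False)
    p_spline = outdir / "mufod_spline.csv"
    pd.DataFrame({"phi_deg": phi, "value": spline}).to_csv(p_spline, index=False)
    record("mufod", [p_mufod, p_spline])

    # --- artificial DWI --------------------------------------------------
    dwi_cfg = config.get("dwi", {})
    dwi = synthesize_dwi(
        field,
        kernel_px=int(dwi_cfg.get("kernel_px", 1)),
        scale=float(dwi_cfg.get("scale", 10.0)),
    )
    paths = export_dwi(dwi, outdir / "dwi")
    record("dwi", paths.values())

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write_png(path: Path, rgb: np.ndarray) -> None:
    from matplotlib.image import imsave

    imsave(path, rgb)


def _jsonable_config(config: dict) -> dict:
    def conv(v):
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        if isinstance(v, Path):
            return str(v)
        return v

    return conv(config)
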