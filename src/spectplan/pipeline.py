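"""The end-to-end plan: segment, register, dose, validate.

Mirrors the clinical flow — atlas segmentation of the subject CT, narrow-band
rigid SPECT–CT registration of the propagated liver contour, kernel
convolution dosimetry on the SPECT grid, dose resampling to CT, and
per-structure DVH/statistics — with every stage's outputs written to disk and
a machine-readable ``plan_summary.json``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io
from .atlas_segmentation import Atlas, load_atlas, segment_with_atlas
from .config import (demons_params_from, dump_config, load_config,
                     regular_step_params_from)
from .dosimetry import (compute_dose, dose_stats, dose_to_ct_grid, dvh,
                        load_kernel_table, plot_dvh, voxelize_kernel)
from .imaging_core import RigidTransform3D, Volume, resample, Grid
from .narrowband_registration import register_rigid_narrowband
from .validation import dice, jaccard, surface_distance_map

log = logging.getLogger("spectplan")


def transform_to_json(t: RigidTransform3D) -> dict:
    return {"rotation_deg": [float(v) for v in t.rotation_deg],
            "translation_mm": [float(v) for v in t.translation_mm],
            "center_mm": [float(v) for v in t.center_mm]}


def transform_from_json(d: dict) -> RigidTransform3D:
    return RigidTransform3D(d["rotation_deg"], d["translation_mm"],
                            d["center_mm"])


def _resample_activity_to_cubic(spect: Volume, spacing: float) -> Volume:
    """Activity on a cubic grid matching the kernel spacing (identity map)."""
    if np.allclose(spect.spacing_mm, spacing):
        return spect
    extent = (np.asarray(spect.data.shape) - 1) * spect.spacing_mm
    shape = tuple(np.ceil(extent / spacing).astype(int) + 1)
    grid = Grid(shape, (spacing,) * 3, spect.origin)
    return resample(spect, grid, None, "linear", background=0.0)


def run_plan(config: dict | str | Path | None, ct_path, spect_path, atlas_dir,
             kernel_path, out_dir, reference_dir=None) -> dict:
    """Execute the full planning chain and write all per-stage outputs.

    Stages run in order (segment -> register -> dose -> validate); a failure
    aborts with the stage name while partial outputs are retained.  The
    summary holds the per-structure DSC/Jaccard against optional reference
    contours, the rigid transform, and per-structure dose statistics.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "resolved_config.yaml")
    kernel_path = Path(kernel_path)
    if not kernel_path.exists():
        raise FileNotFoundError(
            f"kernel file {kernel_path} not found (--kernel)")
    summary: dict = {"stages": []}

    stage = "segment"
    try:
        atlas = atlas_dir if isinstance(atlas_dir, Atlas) else load_atlas(atlas_dir)
        subject_ct = ct_path if isinstance(ct_path, Volume) else io.read_volume(ct_path)
        pp = cfg["preprocessing"]
        seg = segment_with_atlas(atlas, subject_ct, demons_params_from(cfg),
                                 diffusion=pp["anisotropic_diffusion"],
                                 matching=pp["histogram_match"])
        seg_dir = out / "segmentation"
        for name, mask in seg.masks.items():
            io.write_mask(mask, seg_dir / f"{name}.nii.gz")
        io.write_displacement_field(seg.displacement, out / "deformation.nii.gz")
        seg.log.to_csv(out / "demons_iterations.csv", index=False)
        summary["stages"].append(stage)
        summary["structures"] = {n: {"voxels": m.count()}
                                 for n, m in seg.masks.items()}

        stage = "register"
        spect = spect_path if isinstance(spect_path, Volume) \
            else io.read_volume(spect_path)
        nb = cfg["narrowband"]
        transform, trace = register_rigid_narrowband(
            seg.masks["liver"], spect, nb["width_mm"],
            regular_step_params_from(cfg))
        (out / "transform.json").write_text(
            json.dumps(transform_to_json(transform), indent=2))
        trace.to_csv(out / "register_trace.csv", index=False)
        summary["stages"].append(stage)
        summary["transform"] = transform_to_json(transform)

        stage = "dose"
        table = load_kernel_table(kernel_path)
        kernel = voxelize_kernel(table, float(spect.spacing[0]))
        activity = _resample_activity_to_cubic(spect, kernel.spacing_mm)
        scale = cfg["dosimetry"].get("activity_to_dose_scale", 1.0)
        activity = activity.with_data(activity.data * scale)
        dose_spect = compute_dose(activity, kernel)
        dose_ct = dose_to_ct_grid(dose_spect, transform, subject_ct.grid)
        io.write_volume(dose_ct, out / "dose_ct.nii.gz")
        bin_w = cfg["dosimetry"]["bin_width_gy"]
        curves = []
        summary["dose_stats"] = {}
        summary["dvh_files"] = {}
        for name, mask in seg.masks.items():
            if mask.count() == 0:
                continue
            curve = dvh(dose_ct, mask, bin_w, structure=name)
            p = out / "dvh" / f"{name}.csv"
            p.parent.mkdir(parents=True, exist_ok=True)
            curve.to_frame().to_csv(p, index=False)
            summary["dvh_files"][name] = str(p.relative_to(out))
            summary["dose_stats"][name] = dose_stats(dose_ct, mask)
            curves.append(curve)
        plot_dvh(curves, out / "dvh" / "dvh.png")
        summary["stages"].append(stage)

        stage = "validate"
        if reference_dir is not None:
            summary["validation"] = {}
            ref_dir = Path(reference_dir)
            for name, mask in seg.masks.items():
                ref_path = ref_dir / f"{name}.nii.gz"
                if not ref_path.exists() or mask.count() == 0:
                    continue
                ref = io.read_mask(ref_path)
                sd = surface_distance_map(mask, ref)
                summary["validation"][name] = {
                    "dice": dice(mask, ref),
                    "jaccard": jaccard(mask, ref),
                    "mean_surface_distance_mm": sd.mean_mm,
                    "max_surface_distance_mm": sd.max_mm,
                }
            summary["stages"].append(stage)
    except Exception as exc:
        summary["failed_stage"] = stage
        summary["error"] = f"{type(exc).__name__}: {exc}"
        (out / "plan_summary.json").write_text(json.dumps(summary, indent=2))
        raise RuntimeError(f"plan failed at stage {stage!r}: {exc}") from exc

    (out / "plan_summary.json").write_text(json.dumps(summary, indent=2))
    log.info("plan complete: %s", out / "plan_summary.json")
    return summary
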