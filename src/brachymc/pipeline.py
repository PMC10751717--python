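"""End-to-end clinical pipeline on synthetic patients.

Stages mirror a clinical MC workflow: contour + intensity-range material
segmentation, full-scatter water shell, PSF generation for the clinical
source, dwell-plan transport with particle splitting, absolute
normalization, and cumulative DVHs with the standard metrics.

Absolute normalization: the engine scores kerma per emitted-photon
history.  The plan grid is scaled either to deliver the prescription dose
at the prescription point (the default; an exact arithmetic identity by
construction) or through the TG-43-style air-kerma bridge
``N_hist = TRAK / Sk_per_history`` when the plan carries a total reference
air kerma.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .clinical import (MaterialRule, cumulative_dvh, dvh_metrics,
                       structure_mask)
from .engine import generate_psf_records, run_plan_scene
from .fixtures import make_lung_case, make_prostate_case
from .materials import load_spectrum
from .sources import load_source_config, plan_kernel_arrays
from .tallies import DoseGrid, finalize_uncertainty
from .tg43 import EV_PER_G_TO_GY
from .clinical import add_scatter_shell, assign_materials

__all__ = ["segment_case", "normalize_to_prescription",
           "histories_equivalent_for_trak", "run_clinical_case"]

#: pseudo-HU threshold above which body voxels segment as cortical bone
BONE_INTENSITY_RANGE = (300.0, 2000.0)


def segment_case(case, bone: bool = False):
    """Material rules for a synthetic case (worst-case scheme).

    Body is water; rectum / lungs / bronchus are air; with ``bone=True``
    high-intensity voxels inside the body segment as cortical bone.
    """
    body_ranges = ([(BONE_INTENSITY_RANGE[0], BONE_INTENSITY_RANGE[1],
                     "bone_cortical", None)] if bone else [])
    rules = [MaterialRule(structure=None, material="air"),
             MaterialRule(structure="body", material="water",
                          intensity_ranges=body_ranges)]
    for s in case.structures.structures:
        if s.name in ("rectum", "lung_left", "lung_right", "bronchus"):
            rules.append(MaterialRule(structure=s.name, material="air"))
    return assign_materials(case.intensity, case.geometry,
                            case.structures, rules)


def normalize_to_prescription(mean_per_history, geometry, plan):
    """Scale a per-history grid so the prescription point receives the
    prescription dose.  Returns (dose_gy_grid, scale_histories)."""
    idx = geometry.voxel_of(plan.prescription_point)
    if idx is None:
        raise ValueError("prescription point outside the dose grid")
    at_point = float(mean_per_history[idx])
    if at_point <= 0:
        raise ValueError("zero scored dose at the prescription point")
    scale = plan.prescription_dose / (at_point * EV_PER_G_TO_GY)
    return mean_per_history * EV_PER_G_TO_GY * scale, scale


def histories_equivalent_for_trak(trak_ugy_m2, sk_per_history_u_s):
    """Photon histories equivalent to a plan's total reference air kerma."""
    if sk_per_history_u_s <= 0:
        raise ValueError("Sk per history must be > 0")
    return trak_ugy_m2 / sk_per_history_u_s


def run_clinical_case(kind: str = "prostate_like", histories: int = 200_000,
                      seed: int = 1, split_factor: int = 10,
                      bone: bool = False, scatter_shell_cm: float = 20.0,
                      scale: str = "reduced", source: str =
                      "microselectron_v2", outdir=None,
                      n_psf: int | None = None) -> dict:
    """Synthetic clinical case end to end; returns grids, DVHs, metrics."""
    case = (make_prostate_case(seed, scale) if kind == "prostate_like"
            else make_lung_case(seed, scale))
    phantom = segment_case(case, bone=bone)
    shelled = add_scatter_shell(phantom, scatter_shell_cm, "water")
    capsule = load_source_config(source)
    spectrum = load_spectrum("ir192")
    n_psf = n_psf or min(200_000, max(10_000, histories // 5))
    psf = generate_psf_records(capsule, spectrum, n_psf, seed + 101)
    plan_arrays = plan_kernel_arrays(case.plan)
    grid = DoseGrid(geometry=case.geometry, materials=phantom.materials,
                    material_ids=phantom.material_ids,
                    densities=phantom.densities)
    run_plan_scene(shelled, psf, plan_arrays, histories, seed,
                   tlke_grid=grid, split_factor=split_factor)
    mean, rel, _ = finalize_uncertainty(grid)
    dose_gy, scale_hist = normalize_to_prescription(mean, case.geometry,
                                                    case.plan)
    curves = {}
    for s in case.structures.structures:
        mask = structure_mask(s, case.geometry)
        if mask.any():
            curves[s.name] = cumulative_dvh(
                dose_gy, mask, case.geometry.voxel_volume,
                resolution=0.01, structure=s.name)
    target = "prostate" if kind == "prostate_like" else "lung_left"
    metrics = {}
    if target in curves:
        m = dvh_metrics(curves[target], case.plan.prescription_dose)
        metrics[target] = {"V100_pct": m.v100, "V150_pct": m.v150,
                           "V200_pct": m.v200, "D90_Gy": m.d90,
                           "D50_Gy": m.d50}
    if "rectum" in curves:
        m = dvh_metrics(curves["rectum"], case.plan.prescription_dose)
        metrics["rectum"] = {"D2cc_Gy": m.d2cc}
    pidx = case.geometry.voxel_of(case.plan.prescription_point)
    result = {
        "dose_gy": dose_gy,
        "relative_uncertainty": rel,
        "type_a_at_prescription": float(rel[pidx]),
        "curves": curves,
        "metrics": metrics,
        "scale_histories": scale_hist,
        "phantom": phantom,
        "case": case,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, c in curves.items():
            np.savetxt(outdir / f"dvh_{name}.txt",
                       np.column_stack([c.dose_gy, c.volume_pct]),
                       header=f"structure: {name}\ndose_Gy volume_pct")
    return result
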