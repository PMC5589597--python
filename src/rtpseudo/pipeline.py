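"""End-to-end experiment driver at phantom scale.

One experiment mirrors the clinical verification protocol: generate a
DCT/PCT/PMR scan triplet of one synthetic head, synthesize the pseudo-CT,
construct and optimize the 5-beam plan *on the pseudo-CT* (the primary
image), then recompute the same frozen plan on the reference planning CT
and compare: plan metrics and their deltas, pixel dose differences and
gamma agreement on the coronal isocenter plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_core import ImageVolume, RigidTransform, write_volume, write_mask
from .phantom import (PhantomSpec, ScanGeometry, generate_head_phantom,
                      apply_interscan_change, simulate_scan, voxelize,
                      _hu_lut)
from .pseudoct import PseudoCTConfig, generate_pseudo_ct
from .registration import resample_to_grid, resample_mask_to_grid
from .dose import (PlanConfig, make_plan, compute_plan_dose, apply_plan_state,
                   mask_on_grid)
from .evaluate import PlaneROI, plan_metrics, dose_difference, gamma_index

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]

TARGET_SITES = ("ord", "vent", "skull")


@dataclass
class ExperimentConfig:
    """Full, serializable description of one experiment; the seed pins
    every random draw."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    dct_geometry: ScanGeometry = field(default_factory=lambda: ScanGeometry(
        tilt_deg=15.0, slice_thickness=5.0, in_plane_spacing=2.0,
        inferior_cutoff=30.0))
    pct_geometry: ScanGeometry = field(default_factory=lambda: ScanGeometry(
        tilt_deg=0.0, slice_thickness=1.25, in_plane_spacing=2.0))
    pmr_geometry: ScanGeometry = field(default_factory=lambda: ScanGeometry(
        tilt_deg=0.0, slice_thickness=2.5, in_plane_spacing=2.0))
    interscan_delta_mm: float = 2.0
    target_site: str = "ord"            # ord | vent | skull
    pseudo_ct: PseudoCTConfig = field(default_factory=PseudoCTConfig)
    plan: PlanConfig = field(default_factory=PlanConfig)
    dose_criterion_pct: float = 2.0
    distance_criterion_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_site not in TARGET_SITES:
            raise ValueError(f"target_site must be one of {TARGET_SITES}")
        self.phantom.seed = self.seed

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    original_metrics: dict
    verification_metrics: dict
    delta_metrics: dict
    diff: dict
    gamma: dict
    correction_report: dict
    transforms: dict
    artifacts: dict

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "original_metrics": self.original_metrics,
            "verification_metrics": self.verification_metrics,
            "delta_metrics": self.delta_metrics,
            "dose_difference": self.diff,
            "gamma": self.gamma,
            "correction_report": self.correction_report,
            "transforms": self.transforms,
            "artifacts": self.artifacts,
        }


def _fill_sentinel(vol: ImageVolume, value: float = -1000.0) -> ImageVolume:
    return vol.with_data(np.nan_to_num(vol.data, nan=value))


def run_experiment(config: ExperimentConfig,
                   outdir: str | Path | None = None) -> ExperimentResult:
    """Run phantom -> pseudo-CT -> plan -> verification -> comparison."""
    cfg = config
    spec = cfg.phantom

    # ground truth at the planning session
    truth = generate_head_phantom(spec)

    # the diagnostic session saw a (possibly) different outer body;
    # interior anatomy identical, independent noise realization
    labels_dct = apply_interscan_change(truth.labels, cfg.interscan_delta_mm)
    if cfg.interscan_delta_mm == 0:
        ct_diag = truth.ct
    else:
        ct_diag = voxelize(labels_dct, _hu_lut(spec), spec.noise_sigma_hu,
                           spec.seed + 2, "CT")

    dct = simulate_scan(ct_diag, cfg.dct_geometry)
    pct = simulate_scan(truth.ct, cfg.pct_geometry)
    pmr = simulate_scan(truth.mr, cfg.pmr_geometry)

    synth = generate_pseudo_ct(dct, pct, pmr, cfg.pseudo_ct)
    reference = synth.reference_grid

    ptv_truth = truth.structures[f"ptv_{cfg.target_site}"]
    ptv = resample_mask_to_grid(ptv_truth, RigidTransform.identity(), reference)

    plan = make_plan(ptv, synth.unscanned, cfg.plan)
    dose_orig, state = compute_plan_dose(synth.pseudo_ct, plan, ptv)

    # verification: the planning CT on the same grid, same frozen plan
    pct_on_ref = _fill_sentinel(
        resample_to_grid(pct, RigidTransform.identity(), reference))
    dose_ver = apply_plan_state(pct_on_ref, plan, state)

    # same PTV transfer as used inside plan normalization
    ptv_dose = mask_on_grid(ptv, dose_orig)
    m_orig = plan_metrics(dose_orig, ptv_dose)
    m_ver = plan_metrics(dose_ver, ptv_dose)
    deltas = {f"delta_{k}": m_ver.to_dict()[k] - m_orig.to_dict()[k]
              for k in ("d_max", "d_mean", "d_min", "v95", "v100", "ci")}

    iso = plan.beams[0].isocenter
    roi = PlaneROI(center=tuple(iso), axis=1, half_size=50.0)
    diff = dose_difference(dose_orig, dose_ver, roi=roi,
                           criterion=cfg.dose_criterion_pct)
    gamma = gamma_index(dose_orig, dose_ver,
                        dose_criterion=cfg.dose_criterion_pct,
                        distance_criterion=cfg.distance_criterion_mm, roi=roi)

    artifacts: dict = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, vol in (("dct", dct), ("pct", pct), ("pmr", pmr),
                          ("pseudo_ct", synth.pseudo_ct),
                          ("dose_original", dose_orig),
                          ("dose_verification", dose_ver)):
            artifacts[name] = str(write_volume(vol, outdir / f"{name}.nii.gz"))
        artifacts["ptv"] = str(write_mask(ptv, outdir / "ptv.nii.gz"))
        artifacts["unscanned"] = str(
            write_mask(synth.unscanned, outdir / "unscanned.nii.gz"))

    result = ExperimentResult(
        config=cfg,
        original_metrics=m_orig.to_dict(),
        verification_metrics=m_ver.to_dict(),
        delta_metrics=deltas,
        diff=diff.to_dict(),
        gamma=gamma.to_dict(),
        correction_report=synth.report.to_dict(),
        transforms={k: t.as_matrix().tolist() for k, t in synth.transforms.items()},
        artifacts=artifacts,
    )
    if outdir is not None:
        manifest = outdir / "report.json"
        manifest.write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))
        artifacts["report"] = str(manifest)
    return result
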