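"""Pseudo-CT synthesis: body contouring and the outer-body correction scheme.

A prior diagnostic CT (DCT), rigidly aligned into the planning frame, has
the right interior anatomy but generally the wrong outer body: the patient
changed between sessions, and the diagnostic scan may not even cover the
whole planning volume.  The correction replaces every voxel where the two
body shapes disagree with a bulk-equivalent HU:

* *tissue-excessive* voxels — inside the aligned DCT body but outside the
  reference (planning) body — are set to air, -1000 HU;
* *tissue-deficient* voxels — inside the reference body but outside the
  DCT body — are set to soft tissue, 0 HU;
* *unscanned* voxels inside the reference body (anatomy the DCT never
  covered) are likewise deficiencies, set to 0 HU with no attempt to
  recover their true density.

Everything inside both bodies is copied unchanged, so after correction the
pseudo-CT carries the diagnostic scan's interior and the planning scan's
outer body shape, and contains no out-of-scan sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .io_core import (ImageVolume, BinaryMask, RigidTransform, GeometryError,
                      is_sentinel)
from .registration import register_rigid, resample_to_grid

__all__ = [
    "AIR_HU",
    "SOFT_TISSUE_HU",
    "BODY_THRESHOLD_HU",
    "CorrectionReport",
    "PseudoCTConfig",
    "contour_body",
    "detect_unscanned",
    "correct_outer_body",
    "generate_pseudo_ct",
]

AIR_HU = -1000.0          # air-equivalent value for tissue-excessive voxels
SOFT_TISSUE_HU = 0.0      # soft-tissue-equivalent value for deficiencies
BODY_THRESHOLD_HU = -400.0  # default air/tissue split for body contouring


@dataclass
class CorrectionReport:
    """Voxel bookkeeping of one outer-body correction."""

    n_excess: int
    n_deficient: int
    n_unscanned_deficient: int
    n_unchanged: int
    voxel_volume_cc: float

    @property
    def total_voxels(self) -> int:
        return (self.n_excess + self.n_deficient
                + self.n_unscanned_deficient + self.n_unchanged)

    @property
    def excess_cc(self) -> float:
        return self.n_excess * self.voxel_volume_cc

    @property
    def deficient_cc(self) -> float:
        return self.n_deficient * self.voxel_volume_cc

    @property
    def unscanned_deficient_cc(self) -> float:
        return self.n_unscanned_deficient * self.voxel_volume_cc

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(excess_cc=self.excess_cc, deficient_cc=self.deficient_cc,
                 unscanned_deficient_cc=self.unscanned_deficient_cc,
                 total_voxels=self.total_voxels)
        return d


@dataclass
class PseudoCTConfig:
    """Knobs of the synthesis pipeline."""

    body_threshold_hu: float = BODY_THRESHOLD_HU
    mr_body_threshold: float = 60.0     # intensity split for MRI-only mode
    bone_threshold_hu: float = 300.0
    dct_registration_mode: str = "bone-CTCT"  # or "intermodal" (DCT vs PMR)
    mri_only: bool = False              # reference body from the PMR scan


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _fill_holes(mask: np.ndarray) -> np.ndarray:
    out = ndimage.binary_fill_holes(mask)
    # slice-wise fill catches cavities open along the slice axis
    for k in range(out.shape[2]):
        out[:, :, k] = ndimage.binary_fill_holes(out[:, :, k])
    return out


def contour_body(vol: ImageVolume, threshold: float = BODY_THRESHOLD_HU) -> BinaryMask:
    """Delineate the external body by pixel density.

    Largest connected component above ``threshold``, hole-filled in 3D and
    slice-wise.  Out-of-scan sentinel voxels count as below threshold.
    Raises ``GeometryError`` when no voxel exceeds the threshold.
    """
    data = vol.data
    above = np.where(is_sentinel(data), False, data > threshold)
    if not above.any():
        raise GeometryError(
            f"no body found: no voxel above {threshold} in {vol.modality} volume")
    body = _fill_holes(_largest_component(above))
    return BinaryMask.from_volume(vol, body)


def detect_unscanned(dct_aligned: ImageVolume) -> BinaryMask:
    """Voxels of the aligned diagnostic CT the scanner never covered."""
    return BinaryMask.from_volume(dct_aligned, is_sentinel(dct_aligned.data))


def correct_outer_body(dct_aligned: ImageVolume,
                       dct_body: BinaryMask,
                       ref_body: BinaryMask,
                       unscanned: BinaryMask | None = None,
                       ) -> tuple[ImageVolume, CorrectionReport]:
    """Apply the outer-body HU correction on the reference grid.

    Voxel rules, in precedence order:

    a. in ``ref_body`` and unscanned            -> 0 HU (deficiency)
    b. in ``ref_body``, outside ``dct_body``    -> 0 HU (deficiency)
    c. in ``dct_body``, outside ``ref_body``    -> -1000 HU (excess)
    d. outside both bodies                      -> -1000 HU if unscanned/sentinel,
                                                   else copied
    e. inside both bodies, scanned              -> copied unchanged

    The output contains no out-of-scan sentinel.
    """
    for name, m in (("dct_body", dct_body), ("ref_body", ref_body)):
        if not dct_aligned.grid_matches(m):
            raise GeometryError(f"{name} does not share the aligned DCT grid")
    if unscanned is None:
        unscanned = detect_unscanned(dct_aligned)
    elif not dct_aligned.grid_matches(unscanned):
        raise GeometryError("unscanned mask does not share the aligned DCT grid")

    data = dct_aligned.data.astype(float)
    ref = ref_body.data
    dct = dct_body.data
    unsc = unscanned.data | is_sentinel(data)

    deficient_unscanned = ref & unsc
    deficient = ref & ~dct & ~unsc
    excess = dct & ~ref
    out = data.copy()
    out[deficient_unscanned] = SOFT_TISSUE_HU
    out[deficient] = SOFT_TISSUE_HU
    out[excess] = AIR_HU
    outside = ~ref & ~dct
    out[outside & unsc] = AIR_HU

    changed = deficient_unscanned | deficient | excess
    report = CorrectionReport(
        n_excess=int(excess.sum()),
        n_deficient=int(deficient.sum()),
        n_unscanned_deficient=int(deficient_unscanned.sum()),
        n_unchanged=int((~changed).sum()),
        voxel_volume_cc=dct_aligned.voxel_volume_cc,
    )
    assert report.total_voxels == data.size
    pseudo = dct_aligned.with_data(out, modality="CT")
    return pseudo, report


@dataclass
class PseudoCTResult:
    pseudo_ct: ImageVolume
    report: CorrectionReport
    transforms: dict[str, RigidTransform]
    reference_grid: ImageVolume
    unscanned: BinaryMask
    dct_body: BinaryMask
    ref_body: BinaryMask


def generate_pseudo_ct(dct: ImageVolume, pct: ImageVolume | None,
                       pmr: ImageVolume,
                       config: PseudoCTConfig | None = None) -> PseudoCTResult:
    """Run the full synthesis: fuse, register, resample, contour, correct.

    Steps: (1) rigidly fuse the planning MR to the planning CT so both share
    one frame (skipped in MRI-only mode, where the MR frame *is* the
    reference); (2) register the diagnostic CT into that frame; (3) resample
    it onto the planning-MR grid; (4) contour the DCT and reference bodies by
    pixel density; (5) correct tissue excesses/deficiencies/unscanned regions.

    In MRI-only mode (``config.mri_only`` or ``pct is None``) the reference
    body is contoured on the planning MR and the DCT registration is forced
    intermodal.
    """
    cfg = config or PseudoCTConfig()
    mri_only = cfg.mri_only or pct is None
    transforms: dict[str, RigidTransform] = {}

    if mri_only:
        reoriented_pmr = pmr
        transforms["pmr_to_reference"] = RigidTransform.identity()
    else:
        t_pmr = register_rigid(pmr, pct, mode="intermodal")
        transforms["pmr_to_reference"] = t_pmr
        # reorientation: carry the PMR grid into the PCT frame; no resampling
        reoriented_pmr = ImageVolume(
            pmr.data, pmr.spacing, t_pmr.apply(pmr.origin),
            t_pmr.rotation @ pmr.direction, modality="MR")

    if mri_only or cfg.dct_registration_mode == "intermodal":
        t_dct = register_rigid(dct, reoriented_pmr, mode="intermodal")
    else:
        # the reoriented PMR shares the PCT frame, so CT-CT bone matching
        # against the PCT yields the same moving->reference transform
        t_dct = register_rigid(dct, pct, mode="bone-CTCT",
                               bone_threshold_hu=cfg.bone_threshold_hu)
    transforms["dct_to_reference"] = t_dct

    dct_aligned = resample_to_grid(dct, t_dct, reoriented_pmr, method="linear")
    unscanned = detect_unscanned(dct_aligned)
    dct_body = contour_body(dct_aligned, cfg.body_threshold_hu)

    if mri_only:
        ref_body = contour_body(reoriented_pmr, cfg.mr_body_threshold)
    else:
        pct_on_ref = resample_to_grid(pct, RigidTransform.identity(),
                                      reoriented_pmr, method="linear")
        ref_body = contour_body(pct_on_ref, cfg.body_threshold_hu)

    pseudo, report = correct_outer_body(dct_aligned, dct_body, ref_body, unscanned)
    return PseudoCTResult(pseudo_ct=pseudo, report=report, transforms=transforms,
                          reference_grid=reoriented_pmr, unscanned=unscanned,
                          dct_body=dct_body, ref_body=ref_body)
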