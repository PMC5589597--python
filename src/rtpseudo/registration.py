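"""Rigid alignment of scans and resampling onto a common grid.

Two registration modes cover the workflow's needs:

``bone-CTCT``
    CT-to-CT matching of the bony skull: mean-squared HU difference
    restricted to fixed-image voxels above a bone threshold (default
    300 HU).  This is the mode that decides dose accuracy, since the
    skull is the rigid anchor shared by every scan of one head.
``intermodal``
    Mattes mutual information over the whole head, for CT<->MR pairs.

Both run a 3-level multi-resolution pyramid with geometric-center
initialization and a deterministic, seeded sample order, so a given pair
of volumes always yields the same transform.
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk

from .io_core import (SENTINEL, ImageVolume, BinaryMask, RigidTransform,
                      RegistrationError, GeometryError, to_sitk, from_sitk)

__all__ = ["register_rigid", "resample_to_grid", "BONE_HU_THRESHOLD"]

#: Default HU threshold isolating skull from soft tissue for bone matching.
BONE_HU_THRESHOLD = 300.0

_SAMPLING_SEED = 121212  # fixed: registration must be reproducible


def _physical_bounds(vol: ImageVolume) -> tuple[np.ndarray, np.ndarray]:
    n = np.array(vol.shape)
    corners_idx = np.array([[i, j, k] for i in (0, n[0] - 1)
                            for j in (0, n[1] - 1) for k in (0, n[2] - 1)])
    corners = vol.index_to_physical(corners_idx)
    return corners.min(axis=0), corners.max(axis=0)


def _check_overlap(moving: ImageVolume, fixed: ImageVolume) -> None:
    mlo, mhi = _physical_bounds(moving)
    flo, fhi = _physical_bounds(fixed)
    if np.any(mhi < flo) or np.any(mlo > fhi):
        raise RegistrationError(
            f"volumes do not overlap: moving extent [{mlo}, {mhi}] vs "
            f"fixed extent [{flo}, {fhi}]")


def register_rigid(moving: ImageVolume, fixed: ImageVolume,
                   mode: str = "bone-CTCT",
                   bone_threshold_hu: float = BONE_HU_THRESHOLD) -> RigidTransform:
    """Estimate the rigid transform mapping ``moving`` space to ``fixed`` space.

    Parameters
    ----------
    mode
        ``"bone-CTCT"`` (mean-squared difference on the fixed image's bone
        mask; both volumes must be CT-like) or ``"intermodal"`` (Mattes
        mutual information over the head).
    """
    if mode not in ("bone-CTCT", "intermodal"):
        raise ValueError(f"unknown registration mode {mode!r}")
    _check_overlap(moving, fixed)

    mov = np.nan_to_num(moving.data.astype(np.float64), nan=-1000.0)
    fix = np.nan_to_num(fixed.data.astype(np.float64), nan=-1000.0)

    # already at the optimum: identical grids + identical voxels
    if moving.grid_matches(fixed) and np.array_equal(mov, fix):
        return RigidTransform.identity()

    f_img = to_sitk(fixed.with_data(fix))
    m_img = to_sitk(moving.with_data(mov))

    init = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)

    reg = sitk.ImageRegistrationMethod()
    if mode == "bone-CTCT":
        bone = (fix > bone_threshold_hu).astype(np.uint8)
        if not bone.any():
            raise RegistrationError(
                f"no fixed-image voxels above the bone threshold "
                f"({bone_threshold_hu} HU)")
        reg.SetMetricAsMeanSquares()
        reg.SetMetricFixedMask(to_sitk(fixed.with_data(bone, modality="MASK")))
    else:
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.25, _SAMPLING_SEED)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-6, numberOfIterations=500,
        gradientMagnitudeTolerance=1e-8)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(init, inPlace=False)

    # metric scale differs between pyramid levels (smoothing), so divergence
    # is judged within each level: final value must not exceed the level's
    # starting value
    levels: list[list[float]] = []
    reg.AddCommand(sitk.sitkMultiResolutionIterationEvent,
                   lambda: levels.append([]))
    reg.AddCommand(sitk.sitkIterationEvent,
                   lambda: levels[-1].append(reg.GetMetricValue()))

    final = reg.Execute(f_img, m_img)

    if levels and levels[-1]:
        first, last = levels[-1][0], levels[-1][-1]
        if np.isfinite(first) and last > first + abs(first):
            raise RegistrationError(
                f"registration diverged at final level: metric {first:.4g} "
                f"-> {last:.4g}")

    # sitk convention: the estimated transform maps fixed points into the
    # moving image; invert to get our moving->fixed convention.
    if final.GetName() == "CompositeTransform":
        final = sitk.CompositeTransform(final).GetBackTransform()
    euler = sitk.Euler3DTransform(final.Downcast())
    rot = np.asarray(euler.GetMatrix()).reshape(3, 3)
    center = np.asarray(euler.GetCenter())
    trans = np.asarray(euler.GetTranslation())
    # fixed -> moving: p_m = R (p_f - c) + c + t
    fixed_to_moving = RigidTransform(rot, center + trans - rot @ center)
    return fixed_to_moving.inverse()


def resample_to_grid(vol: ImageVolume | BinaryMask,
                     transform: RigidTransform,
                     reference: ImageVolume | BinaryMask,
                     method: str = "linear") -> ImageVolume:
    """Resample ``vol`` through ``transform`` onto ``reference``'s exact grid.

    ``transform`` maps ``vol``'s physical space into the reference space.
    Voxels of the reference grid that map outside ``vol``'s physical extent
    receive the out-of-scan sentinel (``nearest`` method: 0, so masks stay
    binary).
    """
    if method not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation method {method!r}")
    is_mask = isinstance(vol, BinaryMask)
    src = vol.as_volume() if is_mask else vol
    interp = sitk.sitkLinear if method == "linear" else sitk.sitkNearestNeighbor
    default = 0.0 if method == "nearest" else float(SENTINEL)

    ref_vol = reference.as_volume() if isinstance(reference, BinaryMask) else reference
    ref_img = to_sitk(ref_vol.with_data(np.zeros(ref_vol.shape, dtype=np.float32)))
    src_img = to_sitk(src.with_data(src.data.astype(np.float64)))
    # Resample needs the reference->moving map
    t = transform.inverse().to_sitk()
    out_img = sitk.Resample(src_img, ref_img, t, interp, default, sitk.sitkFloat64)
    out = from_sitk(out_img, modality=src.modality)
    if method == "nearest":
        out = out.with_data(np.rint(out.data).astype(src.data.dtype))
    return out


def resample_mask_to_grid(mask: BinaryMask, transform: RigidTransform,
                          reference: ImageVolume | BinaryMask) -> BinaryMask:
    """Nearest-neighbour mask resampling; output stays strictly binary."""
    out = resample_to_grid(mask, transform, reference, method="nearest")
    return BinaryMask.from_volume(out, out.data > 0)
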