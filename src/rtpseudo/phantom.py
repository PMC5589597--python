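"""Synthetic paired head scans (diagnostic CT / planning CT / planning MR).

The generator builds a nested-ellipsoid adult head (scalp | skull | brain |
ventricle) on an isotropic ground-truth grid, voxelizes it to CT (HU) and MR
(arbitrary units) with Gaussian noise, and then emulates the acquisition
differences a prior diagnostic scan brings into the planning workflow:

* the diagnostic CT is thick-sliced (5 mm), gantry-tilted about the
  left-right axis (0-23.3 degrees, as used clinically to spare the
  lenses) and stops short of the
  inferior head, leaving an *unscanned* region;
* the planning CT / MR are untilted thin-slice scans (1.25 / 2.5 mm);
* between the diagnostic and planning sessions the outer body may change
  (weight gain/loss, immobilization gear), modeled as a uniform
  morphological dilation/erosion of the scalp surface with the interior
  anatomy held fixed.

Tissue HU values are standard textbook magnitudes (air -1000, scalp 40,
skull 700, brain 30, CSF 10) and are configurable; the MR table inverts the
bone contrast (skull dark, ventricle bright) as on a T1 image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .io_core import BinaryMask, ImageVolume, GeometryError

__all__ = [
    "PhantomSpec",
    "ScanGeometry",
    "HeadPhantom",
    "generate_head_phantom",
    "apply_interscan_change",
    "simulate_scan",
]

# label codes on the ground-truth grid
AIR, SCALP, SKULL, BRAIN, VENTRICLE = 0, 1, 2, 3, 4

#: Supported gantry-tilt range for diagnostic head CT (lens-sparing
#: tilts), degrees about the L-R axis.
DCT_TILT_RANGE_DEG = (0.0, 23.3)


@dataclass
class PhantomSpec:
    """Anatomy + acquisition-noise parameters of the synthetic head.

    Semi-axes are (L-R, A-P, S-I) in mm.  ``seed`` fully determines the
    generated volumes.
    """

    head_semi_axes: tuple[float, float, float] = (70.0, 85.0, 90.0)
    scalp_thickness: float = 6.0
    skull_thickness: float = 6.0
    ventricle_center: tuple[float, float, float] = (0.0, 0.0, 15.0)
    ventricle_radius: float = 16.0
    hu_table: dict = field(default_factory=lambda: {
        "air": -1000.0, "scalp": 40.0, "skull": 700.0, "brain": 30.0, "csf": 10.0,
    })
    mr_table: dict = field(default_factory=lambda: {
        "air": 5.0, "scalp": 350.0, "skull": 120.0, "brain": 600.0, "csf": 900.0,
    })
    noise_sigma_hu: float = 10.0
    noise_sigma_mr: float = 15.0
    spacing: float = 2.0          # isotropic ground-truth grid, mm
    margin: float = 16.0          # air margin around the head, mm
    ptv_radius: float = 16.0
    seed: int = 0

    def validate(self) -> None:
        a, b, c = self.head_semi_axes
        shell = self.scalp_thickness + self.skull_thickness
        if min(a, b, c) <= 0 or self.scalp_thickness <= 0 or self.skull_thickness <= 0:
            raise GeometryError("semi-axes and shell thicknesses must be positive")
        if min(a, b, c) - shell <= self.ventricle_radius:
            raise GeometryError("ventricle does not fit inside the brain shell")
        for key in ("air", "scalp", "skull", "brain", "csf"):
            if key not in self.hu_table or key not in self.mr_table:
                raise GeometryError(f"tissue table missing label {key!r}")
        if self.spacing <= 0:
            raise GeometryError("grid spacing must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScanGeometry:
    """Acquisition grid of one scan: tilt, slice thickness, coverage."""

    tilt_deg: float = 0.0              # about the L-R (x) axis
    slice_thickness: float = 1.25      # mm, along the (tilted) slice normal
    in_plane_spacing: float = 2.0      # mm
    inferior_cutoff: float = 0.0       # mm of inferior extent not scanned

    def validate(self) -> None:
        if self.slice_thickness <= 0 or self.in_plane_spacing <= 0:
            raise GeometryError("slice thickness and in-plane spacing must be > 0")
        if abs(self.tilt_deg) > 30.0:
            raise GeometryError(f"tilt {self.tilt_deg} outside +/-30 degrees")


@dataclass
class HeadPhantom:
    """Ground-truth bundle: label map, CT, MR, and named structure masks."""

    labels: ImageVolume
    ct: ImageVolume
    mr: ImageVolume
    structures: dict[str, BinaryMask]


def _ellipsoid(xx, yy, zz, center, semi_axes) -> np.ndarray:
    cx, cy, cz = center
    a, b, c = semi_axes
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 + ((zz - cz) / c) ** 2 <= 1.0


def _label_map(spec: PhantomSpec):
    a, b, c = spec.head_semi_axes
    half = np.array([a, b, c]) + spec.margin
    n = np.ceil(2 * half / spec.spacing).astype(int)
    origin = -(n - 1) / 2.0 * spec.spacing  # grid centered on the head
    ax = [origin[d] + spec.spacing * np.arange(n[d]) for d in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")

    t_scalp, t_skull = spec.scalp_thickness, spec.skull_thickness
    labels = np.zeros(tuple(n), dtype=np.uint8)
    labels[_ellipsoid(xx, yy, zz, (0, 0, 0), (a, b, c))] = SCALP
    labels[_ellipsoid(xx, yy, zz, (0, 0, 0),
                      (a - t_scalp, b - t_scalp, c - t_scalp))] = SKULL
    shell = t_scalp + t_skull
    labels[_ellipsoid(xx, yy, zz, (0, 0, 0),
                      (a - shell, b - shell, c - shell))] = BRAIN
    labels[_ellipsoid(xx, yy, zz, spec.ventricle_center,
                      (spec.ventricle_radius,) * 3)] = VENTRICLE
    return labels, origin, (xx, yy, zz)


def _hu_lut(spec: PhantomSpec) -> np.ndarray:
    t = spec.hu_table
    return np.array([t["air"], t["scalp"], t["skull"], t["brain"], t["csf"]])


def _mr_lut(spec: PhantomSpec) -> np.ndarray:
    t = spec.mr_table
    return np.array([t["air"], t["scalp"], t["skull"], t["brain"], t["csf"]])


def voxelize(labels: ImageVolume, lut: np.ndarray, sigma: float, seed: int,
             modality: str) -> ImageVolume:
    """Label map -> scalar volume: LUT values plus seeded Gaussian noise."""
    rng = np.random.default_rng(seed)
    data = lut[labels.data] + rng.normal(0.0, sigma, size=labels.shape)
    return labels.with_data(data, modality=modality)


def generate_head_phantom(spec: PhantomSpec) -> HeadPhantom:
    """Build the ground-truth head: labels, CT, MR, structure masks.

    Structures: ``body``, ``skull``, ``brain``, ``ventricle`` plus three
    PTV spheres — ``ptv_ord`` at an ordinary deep-brain site, ``ptv_vent``
    abutting the ventricle, ``ptv_skull`` abutting the inner skull surface.
    """
    spec.validate()
    labels_arr, origin, (xx, yy, zz) = _label_map(spec)
    labels = ImageVolume(labels_arr, (spec.spacing,) * 3, origin, modality="MASK")

    ct = voxelize(labels, _hu_lut(spec), spec.noise_sigma_hu, spec.seed, "CT")
    mr = voxelize(labels, _mr_lut(spec), spec.noise_sigma_mr, spec.seed + 1, "MR")

    a, b, c = spec.head_semi_axes
    shell = spec.scalp_thickness + spec.skull_thickness
    r = spec.ptv_radius
    vc = np.asarray(spec.ventricle_center, dtype=float)
    # ordinary site: deep brain, off-axis, away from both ventricle and skull
    ord_center = (-(a - shell) * 0.45, (b - shell) * 0.35, -5.0)
    # ventricle-abutting: sphere tangent to the ventricle surface
    vent_center = vc + np.array([spec.ventricle_radius + r, 0.0, 0.0])
    # skull-abutting: tangent to the inner-skull ellipsoid along +y
    skull_center = (0.0, (b - shell) - r, 0.0)

    def mask(arr):
        return BinaryMask.from_volume(labels, arr)

    structures = {
        "body": mask(labels_arr > AIR),
        "skull": mask(labels_arr == SKULL),
        "brain": mask((labels_arr == BRAIN) | (labels_arr == VENTRICLE)),
        "ventricle": mask(labels_arr == VENTRICLE),
        "ptv_ord": mask(_ellipsoid(xx, yy, zz, ord_center, (r,) * 3)),
        "ptv_vent": mask(_ellipsoid(xx, yy, zz, vent_center, (r,) * 3)),
        "ptv_skull": mask(_ellipsoid(xx, yy, zz, skull_center, (r,) * 3)),
    }
    return HeadPhantom(labels=labels, ct=ct, mr=mr, structures=structures)


def apply_interscan_change(labels: ImageVolume, delta_scalp_mm: float) -> ImageVolume:
    """Dilate (delta>0) or erode (delta<0) the outer body surface by |delta| mm.

    Models the body change between the diagnostic and planning sessions.
    Voxels interior to the scalp (skull, brain, ventricle) are never touched;
    an erosion that would cut into non-scalp tissue raises ``GeometryError``.
    """
    arr = labels.data
    spacing = labels.spacing
    if delta_scalp_mm == 0:
        return labels.copy()
    body = arr > AIR
    out = arr.copy()
    # EDT measures center-to-center distance; the body surface lies half a
    # voxel beyond the boundary voxel centers, so a voxel changes side when
    # its center is within delta of the surface: edt <= delta + spacing/2
    half = float(np.mean(spacing)) / 2.0
    if delta_scalp_mm > 0:
        dist = ndimage.distance_transform_edt(~body, sampling=spacing)
        out[(dist > 0) & (dist <= delta_scalp_mm + half)] = SCALP
    else:
        dist = ndimage.distance_transform_edt(body, sampling=spacing)
        shed = body & (dist <= -delta_scalp_mm + half)
        if np.any(arr[shed] != SCALP):
            raise GeometryError(
                f"erosion of {-delta_scalp_mm} mm cuts below the scalp layer")
        out[shed] = AIR
    return labels.with_data(out)


def _tilt_rotation(tilt_deg: float) -> np.ndarray:
    """Rotation about the L-R (x) axis by the gantry tilt."""
    t = np.deg2rad(tilt_deg)
    ct, st = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, ct, -st], [0.0, st, ct]])


def simulate_scan(vol: ImageVolume, geom: ScanGeometry) -> ImageVolume:
    """Resample a ground-truth volume onto an acquisition grid.

    The output grid's slice normal is tilted by ``geom.tilt_deg`` about the
    L-R axis, slice spacing is ``geom.slice_thickness``, and slices whose
    centers lie within ``geom.inferior_cutoff`` mm of the inferior edge of
    the source volume are absent (the unscanned region).  The source is
    box-averaged along its slice axis first to emulate the finite slice
    sensitivity profile, then linearly interpolated.
    """
    import SimpleITK as sitk

    from .io_core import from_sitk, to_sitk

    geom.validate()
    rot = _tilt_rotation(geom.tilt_deg)
    direction = rot @ vol.direction

    # physical corners of the source, expressed in the tilted frame
    n = np.array(vol.shape)
    corners_idx = np.array([[i, j, k] for i in (0, n[0] - 1)
                            for j in (0, n[1] - 1) for k in (0, n[2] - 1)])
    corners = vol.index_to_physical(corners_idx)
    center = corners.mean(axis=0)
    local = (corners - center) @ direction  # coordinates along tilted axes
    lo, hi = local.min(axis=0), local.max(axis=0)

    out_spacing = np.array([geom.in_plane_spacing, geom.in_plane_spacing,
                            geom.slice_thickness])
    size = np.maximum(np.floor((hi - lo) / out_spacing).astype(int) + 1, 1)
    origin = center + direction @ lo

    # slice-axis box averaging (anti-aliasing for thick slices)
    width = max(int(round(geom.slice_thickness / vol.spacing[2])), 1)
    data = vol.data.astype(float)
    if width > 1:
        data = ndimage.uniform_filter1d(data, size=width, axis=2, mode="nearest")
    fill = float(np.min(data))  # air-equivalent background of this modality
    src = to_sitk(vol.with_data(data))

    ref = sitk.Image([int(s) for s in size], sitk.sitkFloat64)
    ref.SetSpacing(tuple(float(s) for s in out_spacing))
    ref.SetOrigin(tuple(float(o) for o in origin))
    ref.SetDirection(tuple(float(d) for d in direction.ravel()))
    res = sitk.Resample(src, ref, sitk.Transform(), sitk.sitkLinear, fill,
                        sitk.sitkFloat64)
    out = from_sitk(res, modality=vol.modality)

    if geom.inferior_cutoff > 0:
        # drop slices whose center-plane z is below the cutoff
        k = np.arange(out.shape[2])
        slice_centers = out.index_to_physical(
            np.stack([np.full_like(k, (out.shape[0] - 1) / 2.0),
                      np.full_like(k, (out.shape[1] - 1) / 2.0), k], axis=1))
        z_floor = corners[:, 2].min() + geom.inferior_cutoff
        keep = slice_centers[:, 2] >= z_floor
        if not np.any(keep):
            raise GeometryError("inferior cutoff removes the entire scan")
        first = int(np.argmax(keep))
        new_origin = out.index_to_physical(np.array([0.0, 0.0, float(first)]))
        out = ImageVolume(out.data[:, :, first:], out.spacing, new_origin,
                          out.direction, modality=out.modality)
    return out
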