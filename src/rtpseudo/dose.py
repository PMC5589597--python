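"""Simplified heterogeneity-aware photon dose engine and plan construction.

The engine models the primary photon fluence of a megavoltage beam:

    D(p) = w * exp(-mu * d_eff(p)) * (SAD / r(p))^2 * f_lat(p)

with ``d_eff`` the radiological (water-equivalent) depth from the patient
surface to ``p`` (line integral of relative electron density), ``r`` the
distance to the source, and ``f_lat`` a Gaussian-penumbra field aperture
evaluated in the isocenter plane.  Scatter kernels are deliberately out of
scope: the model is desk-scale and deterministic yet fully sensitive to
tissue heterogeneity, which is the property a pseudo-CT must get right.

Doses are dimensionless beam outputs until plan normalization, after which
the grid is expressed in percent of the prescription dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .io_core import ImageVolume, BinaryMask, GeometryError, PlanningError, is_sentinel

__all__ = [
    "BeamSpec",
    "PlanConfig",
    "Plan",
    "PlanState",
    "hu_to_density",
    "density_from_ct",
    "radiological_path",
    "compute_beam_dose",
    "make_plan",
    "compute_plan_dose",
    "apply_plan_state",
    "dose_at_volume",
]

# HU -> relative electron density calibration anchors (piecewise linear,
# clamped outside): air, water/soft tissue, dense bone.
_HU_ANCHORS = np.array([-1000.0, 0.0, 1500.0])
_RED_ANCHORS = np.array([0.0, 1.0, 1.85])


def hu_to_density(hu):
    """Relative electron density from HU; rejects out-of-scan sentinels."""
    hu = np.asarray(hu, dtype=float)
    if np.any(np.isnan(hu)):
        raise ValueError("sentinel (out-of-scan) HU encountered; the volume "
                         "must be corrected before dose calculation")
    return np.interp(hu, _HU_ANCHORS, _RED_ANCHORS)


def density_from_ct(ct: ImageVolume) -> ImageVolume:
    if ct.modality != "CT":
        raise ValueError("density conversion expects a CT-like volume")
    return ct.with_data(hu_to_density(ct.data), modality="CT")


@dataclass
class BeamSpec:
    """One static photon beam."""

    gantry_deg: float
    couch_deg: float = 0.0
    sad: float = 1000.0                 # source-axis distance, mm
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    field_size: float = 50.0            # square field side at isocenter, mm
    weight: float = 1.0
    mu_per_cm: float = 0.05             # primary attenuation in water, 1/cm
    penumbra_sigma: float = 3.0         # mm at the isocenter plane

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("beam weight must be >= 0")
        if self.field_size <= 0 or self.mu_per_cm <= 0 or self.sad <= 0:
            raise ValueError("field size, mu and SAD must be positive")

    @property
    def source_position(self) -> np.ndarray:
        """Source location: gantry rotates in the axial plane, couch about
        the vertical (A-P) axis."""
        g = math.radians(self.gantry_deg)
        c = math.radians(self.couch_deg)
        d = np.array([math.sin(g), -math.cos(g), 0.0])
        ry = np.array([[math.cos(c), 0.0, math.sin(c)],
                       [0.0, 1.0, 0.0],
                       [-math.sin(c), 0.0, math.cos(c)]])
        return np.asarray(self.isocenter, dtype=float) + self.sad * (ry @ d)

    def to_dict(self) -> dict:
        return asdict(self)


# -- radiological depth ---------------------------------------------------

def radiological_path(density: ImageVolume, src, dst) -> float:
    """Exact Siddon line integral of density from ``src`` to ``dst`` (cm).

    Both points in physical mm; voxels are treated as homogeneous boxes and
    every boundary crossing contributes its exact segment length.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    length_mm = float(np.linalg.norm(dst - src))
    if length_mm == 0.0:
        raise GeometryError("zero-length ray")

    p0 = density.physical_to_index(src)
    p1 = density.physical_to_index(dst)
    d = p1 - p0
    n = np.array(density.shape)

    t0, t1 = 0.0, 1.0
    for a in range(3):
        lo, hi = -0.5, n[a] - 0.5
        if d[a] == 0.0:
            if not (lo <= p0[a] <= hi):
                return 0.0
            continue
        ta, tb = (lo - p0[a]) / d[a], (hi - p0[a]) / d[a]
        t0 = max(t0, min(ta, tb))
        t1 = min(t1, max(ta, tb))
    if t0 >= t1:
        return 0.0

    alphas = [np.array([t0, t1])]
    for a in range(3):
        if d[a] == 0.0:
            continue
        m = np.arange(0, n[a] + 1)
        ts = (m - 0.5 - p0[a]) / d[a]
        alphas.append(ts[(ts > t0) & (ts < t1)])
    ts = np.unique(np.concatenate(alphas))
    mids = (ts[:-1] + ts[1:]) / 2.0
    seg = np.diff(ts) * length_mm  # mm
    idx = np.rint(p0 + np.outer(mids, d)).astype(int)
    idx = np.clip(idx, 0, n - 1)
    dens = density.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return float(np.sum(dens * seg)) / 10.0  # mm -> cm


def _depth_map(density: ImageVolume, source: np.ndarray, points: np.ndarray,
               step_mm: float = 1.0, chunk: int = 20000) -> np.ndarray:
    """Radiological depth (cm) from box entry to each point, vectorized.

    Uniform midpoint sampling along each ray at ~``step_mm`` resolution;
    exact for homogeneous media and within a fraction of a voxel otherwise.
    """
    n = np.array(density.shape)
    src_idx = density.physical_to_index(source)
    out = np.zeros(len(points))
    data = np.ascontiguousarray(density.data.astype(np.float32))
    for lo in range(0, len(points), chunk):
        pts = points[lo:lo + chunk]
        pidx = density.physical_to_index(pts)
        dvec = pidx - src_idx
        t0 = np.zeros(len(pts))
        t1 = np.ones(len(pts))
        for a in range(3):
            da = dvec[:, a]
            with np.errstate(divide="ignore", invalid="ignore"):
                ta = (-0.5 - src_idx[a]) / da
                tb = (n[a] - 0.5 - src_idx[a]) / da
            tmin = np.where(da != 0, np.minimum(ta, tb), -np.inf)
            tmax = np.where(da != 0, np.maximum(ta, tb), np.inf)
            inside = (-0.5 <= src_idx[a]) & (src_idx[a] <= n[a] - 0.5)
            if not inside:
                tmin = np.where(da != 0, tmin, np.inf)
            t0 = np.maximum(t0, tmin)
            t1 = np.minimum(t1, tmax)
        t1 = np.minimum(t1, 1.0)
        seg_mm = np.linalg.norm(pts - source, axis=1) * np.maximum(t1 - t0, 0.0)
        nk = max(int(math.ceil(seg_mm.max() / step_mm)) if seg_mm.size else 1, 8)
        frac = (np.arange(nk) + 0.5) / nk
        valid = t1 > t0
        ts = t0[:, None] + (t1 - t0)[:, None] * frac[None, :]
        sample_idx = src_idx[None, None, :] + ts[:, :, None] * dvec[:, None, :]
        # integration is clipped to the voxel box, so edge extension (not
        # zero fill) keeps boundary samples consistent with the Siddon
        # box model used by radiological_path
        vals = ndimage.map_coordinates(
            data, sample_idx.reshape(-1, 3).T, order=1, mode="nearest")
        mean_dens = vals.reshape(len(pts), nk).mean(axis=1)
        out[lo:lo + chunk] = np.where(valid, mean_dens * seg_mm / 10.0, 0.0)
    return out


def _beam_basis(beam: BeamSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    src = beam.source_position
    iso = np.asarray(beam.isocenter, dtype=float)
    axis = (iso - src) / np.linalg.norm(iso - src)
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(axis, up)) > 0.9:
        up = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, up)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return axis, e1, e2


def compute_beam_dose(density: ImageVolume, beam: BeamSpec,
                      grid: ImageVolume | None = None,
                      inverse_square: bool = True,
                      penumbra: bool = True,
                      step_mm: float = 1.0) -> ImageVolume:
    """Dose of a single beam on ``grid`` (default: the density grid)."""
    if np.any(is_sentinel(density.data)):
        raise ValueError("density volume contains out-of-scan sentinels")
    grid = grid if grid is not None else density
    src = beam.source_position
    iso = np.asarray(beam.isocenter, dtype=float)
    axis, e1, e2 = _beam_basis(beam)

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in grid.shape), indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    pts = grid.index_to_physical(idx)

    v = pts - src
    depth_along = v @ axis
    downstream = depth_along > 1e-6
    r = np.linalg.norm(v, axis=1)

    dose = np.zeros(len(pts))
    if np.any(downstream):
        p_d = pts[downstream]
        scale = beam.sad / depth_along[downstream]
        xl = (v[downstream] @ e1) * scale
        yl = (v[downstream] @ e2) * scale
        hw = beam.field_size / 2.0
        if penumbra:
            s = beam.penumbra_sigma * math.sqrt(2.0)
            f = (0.5 * (erf((hw - xl) / s) + erf((hw + xl) / s))
                 * 0.5 * (erf((hw - yl) / s) + erf((hw + yl) / s)))
        else:
            f = ((np.abs(xl) <= hw) & (np.abs(yl) <= hw)).astype(float)
        in_field = f > 1e-9
        d_eff = np.zeros(len(p_d))
        if np.any(in_field):
            d_eff[in_field] = _depth_map(density, src, p_d[in_field], step_mm)
        att = np.exp(-beam.mu_per_cm * d_eff)
        isq = (beam.sad / r[downstream]) ** 2 if inverse_square else 1.0
        dose[downstream] = beam.weight * att * isq * f
    return grid.with_data(dose.reshape(grid.shape), modality="DOSE")


# -- plan construction ----------------------------------------------------

@dataclass
class PlanConfig:
    """Beam-geometry and optimization knobs of the 5-beam plan."""

    coplanar_gantry_deg: tuple[float, ...] = (40.0, 110.0, 250.0, 320.0)
    noncoplanar_gantry_deg: float = 20.0
    noncoplanar_couch_deg: float = 45.0
    sad: float = 1000.0
    mu_per_cm: float = 0.05
    penumbra_sigma: float = 3.0
    field_margin: float = 8.0           # mm added around the PTV extent
    avoidance_step_deg: float = 5.0
    max_ptv_dose_pct: float = 110.0     # planning criterion: Max PTV <= 110%
    max_weight_iterations: int = 50
    dose_grid_spacing: float = 2.5      # mm, isotropic
    depth_step_mm: float = 1.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Plan:
    """A beam set; dose is reported in % of the prescription (100 = Rx)."""

    beams: list[BeamSpec]
    config: PlanConfig = field(default_factory=PlanConfig)

    def __post_init__(self) -> None:
        if not self.beams:
            raise PlanningError("a plan needs at least one beam")

    def to_dict(self) -> dict:
        return {"beams": [b.to_dict() for b in self.beams],
                "config": self.config.to_dict()}


@dataclass
class PlanState:
    """Frozen optimization result: reapplied unchanged for verification."""

    weights: np.ndarray
    normalization: float   # global factor taking the weighted sum to % Rx

    def to_dict(self) -> dict:
        return {"weights": list(map(float, self.weights)),
                "normalization": float(self.normalization)}


def _ray_blocked(unscanned: BinaryMask, src: np.ndarray, iso: np.ndarray,
                 n_samples: int = 256) -> bool:
    if not unscanned.data.any():
        return False
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = src[None, :] + ts[:, None] * (iso - src)[None, :]
    idx = np.rint(unscanned.physical_to_index(pts)).astype(int)
    n = np.array(unscanned.shape)
    ok = np.all((idx >= 0) & (idx < n), axis=1)
    if not ok.any():
        return False
    sub = idx[ok]
    return bool(unscanned.data[sub[:, 0], sub[:, 1], sub[:, 2]].any())


def make_plan(ptv: BinaryMask, unscanned: BinaryMask | None = None,
              config: PlanConfig | None = None) -> Plan:
    """Build the 5-beam arrangement: 4 coplanar + 1 non-coplanar.

    Isocenter at the PTV centroid; the square field covers the PTV extent
    plus a margin.  Any beam whose entry ray (source to isocenter) crosses
    the unscanned region is rotated in gantry by the smallest admissible
    multiple of ``avoidance_step_deg``.
    """
    cfg = config or PlanConfig()
    if not ptv.data.any():
        raise PlanningError("PTV mask is empty")
    idx = np.argwhere(ptv.data)
    iso = ptv.index_to_physical(idx.astype(float)).mean(axis=0)
    extent = ptv.index_to_physical(idx.astype(float))
    span = float((extent.max(axis=0) - extent.min(axis=0)).max())
    fsize = span + 2.0 * cfg.field_margin

    geometries = [(g, 0.0) for g in cfg.coplanar_gantry_deg]
    geometries.append((cfg.noncoplanar_gantry_deg, cfg.noncoplanar_couch_deg))
    if len(geometries) != 5:
        raise PlanningError("expected 4 coplanar + 1 non-coplanar beam")

    beams = []
    for g0, couch in geometries:
        chosen = None
        offsets = [0.0]
        k = 1
        while cfg.avoidance_step_deg * k < 180.0:
            offsets += [cfg.avoidance_step_deg * k, -cfg.avoidance_step_deg * k]
            k += 1
        for off in offsets:
            beam = BeamSpec(gantry_deg=(g0 + off) % 360.0, couch_deg=couch,
                            sad=cfg.sad, isocenter=tuple(iso), field_size=fsize,
                            weight=1.0, mu_per_cm=cfg.mu_per_cm,
                            penumbra_sigma=cfg.penumbra_sigma)
            if unscanned is None or not _ray_blocked(unscanned,
                                                     beam.source_position, iso):
                chosen = beam
                break
        if chosen is None:
            raise PlanningError(
                f"no admissible gantry angle for beam at {g0} deg "
                f"(couch {couch}): every entry ray crosses the unscanned region")
        beams.append(chosen)
    return Plan(beams=beams, config=cfg)


def _dose_grid_geometry(ct: ImageVolume, spacing: float) -> ImageVolume:
    """Coarsened axis-aligned grid covering the CT extent."""
    n = np.array(ct.shape)
    corners_idx = np.array([[i, j, k] for i in (0, n[0] - 1)
                            for j in (0, n[1] - 1) for k in (0, n[2] - 1)])
    corners = ct.index_to_physical(corners_idx)
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    size = np.maximum(np.floor((hi - lo) / spacing).astype(int) + 1, 1)
    return ImageVolume(np.zeros(tuple(size), dtype=np.float32),
                       (spacing,) * 3, lo, np.eye(3), modality="DOSE")


def dose_at_volume(dose_vals: np.ndarray, volume_pct: float) -> float:
    """DVH order statistic: dose received by at least ``volume_pct`` of voxels.

    Returns the value at descending rank ceil(volume_pct/100 * n), so exactly
    that fraction (up to one voxel) receives at least the returned dose.
    """
    vals = np.asarray(dose_vals, dtype=float).ravel()
    nvox = vals.size
    if nvox == 0:
        raise ValueError("empty dose sample")
    k = int(math.ceil(volume_pct / 100.0 * nvox))
    k = min(max(k, 1), nvox)
    return float(np.partition(vals, nvox - k)[nvox - k])


def mask_on_grid(mask: BinaryMask, grid: ImageVolume) -> BinaryMask:
    """Nearest-neighbour transfer of a mask onto another axis-aligned grid."""
    return BinaryMask.from_volume(grid, _resample_mask_nearest(mask, grid))


def _resample_mask_nearest(mask: BinaryMask, grid: ImageVolume) -> np.ndarray:
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in grid.shape), indexing="ij")
    pts = grid.index_to_physical(
        np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1))
    idx = np.rint(mask.physical_to_index(pts)).astype(int)
    n = np.array(mask.shape)
    inside = np.all((idx >= 0) & (idx < n), axis=1)
    out = np.zeros(len(pts), dtype=bool)
    sub = idx[inside]
    out[inside] = mask.data[sub[:, 0], sub[:, 1], sub[:, 2]]
    return out.reshape(grid.shape)


def compute_plan_dose(ct: ImageVolume, plan: Plan, ptv: BinaryMask,
                      ) -> tuple[ImageVolume, PlanState]:
    """Optimize beam weights and normalize; dose in % of prescription.

    Per-beam weights start from equalized mean PTV contributions and are
    multiplicatively reduced (bounded loop) until the maximum PTV dose is
    within the 110% planning limit; the final global normalization sets
    D95(PTV) = 100 exactly, so the 100% isodose covers 95% of the target.
    """
    cfg = plan.config
    grid = _dose_grid_geometry(ct, cfg.dose_grid_spacing)
    density = density_from_ct(ct)
    beam_doses = [compute_beam_dose(density, b, grid=grid,
                                    step_mm=cfg.depth_step_mm).data
                  for b in plan.beams]
    ptv_grid = _resample_mask_nearest(ptv, grid)
    if not ptv_grid.any():
        raise PlanningError("PTV does not intersect the dose grid")

    means = np.array([bd[ptv_grid].mean() for bd in beam_doses])
    if np.any(means <= 0):
        raise PlanningError("a beam delivers no dose to the PTV "
                            "(PTV outside its field)")
    weights = np.array([b.weight for b in plan.beams]) / means

    total = None
    for _ in range(cfg.max_weight_iterations):
        total = sum(w * bd for w, bd in zip(weights, beam_doses))
        vals = total[ptv_grid]
        scale = 100.0 / dose_at_volume(vals, 95.0)
        if vals.max() * scale <= cfg.max_ptv_dose_pct:
            break
        hot = np.unravel_index(np.argmax(np.where(ptv_grid, total, -np.inf)),
                               total.shape)
        contrib = [w * bd[hot] for w, bd in zip(weights, beam_doses)]
        weights[int(np.argmax(contrib))] *= 0.9
    total = sum(w * bd for w, bd in zip(weights, beam_doses))
    scale = 100.0 / dose_at_volume(total[ptv_grid], 95.0)
    state = PlanState(weights=weights, normalization=scale)
    return grid.with_data(total * scale, modality="DOSE"), state


def apply_plan_state(ct: ImageVolume, plan: Plan, state: PlanState,
                     ) -> ImageVolume:
    """Recompute the plan's dose on another CT with weights and
    normalization frozen — the verification-plan contract."""
    cfg = plan.config
    grid = _dose_grid_geometry(ct, cfg.dose_grid_spacing)
    density = density_from_ct(ct)
    total = None
    for w, beam in zip(state.weights, plan.beams):
        bd = compute_beam_dose(density, beam, grid=grid,
                               step_mm=cfg.depth_step_mm).data
        total = w * bd if total is None else total + w * bd
    return grid.with_data(total * state.normalization, modality="DOSE")
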