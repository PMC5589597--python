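"""Feasibility metrics: DVH, plan-quality indicators, pixel dose
differences and gamma agreement between two dose grids.

All doses are in percent of the prescription and all dose criteria use
*global* normalization (percent points of the prescription, not of the
local dose).  The default evaluation region is the 10 x 10 cm coronal
plane through the plan isocenter; pass ``roi=None`` for full-volume maps.

Gamma is the combined dose-difference / distance-to-agreement index

    gamma(p) = min_q sqrt( (D_e(q) - D_r(p))^2 / dD^2 + |q - p|^2 / dr^2 )

searched exhaustively over an interpolated sub-grid of the evaluated dose
(step <= dr/10) within a radius of 3*dr around each reference pixel;
gamma <= 1 means agreement within the (dD %, dr mm) criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .io_core import ImageVolume, BinaryMask, GeometryError

__all__ = [
    "PlanMetrics",
    "DiffResult",
    "GammaResult",
    "PlaneROI",
    "dvh",
    "plan_metrics",
    "dose_difference",
    "gamma_index",
]


@dataclass
class PlanMetrics:
    """Plan-quality indicators over the PTV (doses in % of prescription)."""

    d_min: float
    d_mean: float
    d_max: float
    v95: float    # % of PTV receiving >= 95%
    v100: float   # % of PTV receiving >= 100%
    ci: float     # conformity: volume(dose >= 100%) / PTV volume, ideal 1.0

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


@dataclass
class DiffResult:
    """Pixel-to-pixel dose differences (evaluated - reference), % points."""

    diff: np.ndarray        # signed difference map on the ROI
    mean_abs: float
    sigma: float            # std of |diff|
    max_abs: float
    passing_rate: float     # % of pixels with |diff| <= criterion
    criterion: float

    def to_dict(self) -> dict:
        return {"mean_abs": float(self.mean_abs), "sigma": float(self.sigma),
                "max_abs": float(self.max_abs),
                "passing_rate": float(self.passing_rate),
                "criterion": float(self.criterion)}


@dataclass
class GammaResult:
    """Gamma agreement map and its summary statistics."""

    gamma: np.ndarray
    mean: float
    sigma: float
    max: float
    passing_rate: float     # % of evaluated pixels with gamma <= 1
    dose_criterion: float   # % points
    distance_criterion: float  # mm

    def to_dict(self) -> dict:
        return {"mean": float(self.mean), "sigma": float(self.sigma),
                "max": float(self.max), "passing_rate": float(self.passing_rate),
                "dose_criterion": float(self.dose_criterion),
                "distance_criterion": float(self.distance_criterion)}


@dataclass
class PlaneROI:
    """Axis-aligned square plane: ``axis`` is the normal (0=x sagittal,
    1=y coronal, 2=z axial), centered on ``center`` (mm), ``half_size`` mm."""

    center: tuple[float, float, float]
    axis: int = 1
    half_size: float = 50.0


def dvh(dose: ImageVolume, mask: BinaryMask, bin_width: float = 0.5,
        ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative dose-volume histogram.

    Returns ``(levels, volume_pct)`` with ``volume_pct[i]`` the percent of
    the structure receiving at least ``levels[i]``; monotone non-increasing
    and 100 at level 0.
    """
    if not dose.grid_matches(mask):
        raise GeometryError("dose and mask are not on the same grid")
    vals = dose.data[mask.data]
    if vals.size == 0:
        raise GeometryError("empty structure mask")
    top = float(vals.max())
    levels = np.arange(0.0, top + 2 * bin_width, bin_width)
    volume = 100.0 * (vals[None, :] >= levels[:, None]).mean(axis=1)
    return levels, volume


def plan_metrics(dose: ImageVolume, ptv: BinaryMask) -> PlanMetrics:
    """Min/mean/max PTV dose, V95%, V100% and the conformity index.

    CI = (total volume receiving >= 100% prescription) / (PTV volume); the
    ideal value is 1.0 and values above 1 mean dose spills outside the PTV.
    """
    if not dose.grid_matches(ptv):
        raise GeometryError("dose and PTV are not on the same grid")
    vals = dose.data[ptv.data]
    if vals.size == 0:
        raise GeometryError("empty PTV mask")
    irradiated = int((dose.data >= 100.0).sum())
    return PlanMetrics(
        d_min=float(vals.min()),
        d_mean=float(vals.mean()),
        d_max=float(vals.max()),
        v95=float(100.0 * (vals >= 95.0).mean()),
        v100=float(100.0 * (vals >= 100.0).mean()),
        ci=float(irradiated / vals.size),
    )


def _extract_plane(dose: ImageVolume, roi: PlaneROI,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROI pixels of the plane: 2D dose array + the two in-plane physical
    coordinate vectors (mm).  Requires an axis-aligned grid."""
    if not np.allclose(dose.direction, np.eye(3), atol=1e-6):
        raise GeometryError("plane extraction expects an axis-aligned dose grid")
    ax = roi.axis
    center = np.asarray(roi.center, dtype=float)
    k = int(np.rint((center[ax] - dose.origin[ax]) / dose.spacing[ax]))
    if not (0 <= k < dose.shape[ax]):
        raise GeometryError("ROI plane lies outside the dose grid")
    in_plane = [a for a in range(3) if a != ax]
    sl = [slice(None)] * 3
    sl[ax] = k
    plane = dose.data[tuple(sl)]
    coords = []
    keep = []
    for a in in_plane:
        c = dose.origin[a] + dose.spacing[a] * np.arange(dose.shape[a])
        sel = np.abs(c - center[a]) <= roi.half_size
        coords.append(c[sel])
        keep.append(sel)
    plane = plane[np.ix_(keep[0], keep[1])]
    return plane, coords[0], coords[1]


def dose_difference(reference: ImageVolume, evaluated: ImageVolume,
                    roi: PlaneROI | None = None,
                    criterion: float = 2.0) -> DiffResult:
    """Pixel-to-pixel dose difference (evaluated - reference) on the ROI."""
    if not reference.grid_matches(evaluated):
        raise GeometryError("dose grids do not match")
    if roi is None:
        ref = reference.data
        ev = evaluated.data
    else:
        ref, _, _ = _extract_plane(reference, roi)
        ev, _, _ = _extract_plane(evaluated, roi)
    diff = ev - ref
    absd = np.abs(diff)
    return DiffResult(
        diff=diff,
        mean_abs=float(absd.mean()),
        sigma=float(absd.std()),
        max_abs=float(absd.max()),
        passing_rate=float(100.0 * (absd <= criterion).mean()),
        criterion=criterion,
    )


def _gamma_plane(ref: np.ndarray, ev: np.ndarray,
                 u: np.ndarray, v: np.ndarray,
                 dose_crit: float, dist_crit: float,
                 subgrid_divisions: int = 10,
                 search_factor: float = 3.0) -> np.ndarray:
    """Exhaustive 2D gamma of ``ev`` against ``ref`` on shared coordinates."""
    step = dist_crit / subgrid_divisions
    radius = search_factor * dist_crit
    m = int(math.floor(radius / step))
    offs = step * np.arange(-m, m + 1)
    du, dv = np.meshgrid(offs, offs, indexing="ij")
    keep = du ** 2 + dv ** 2 <= radius ** 2
    du, dv = du[keep], dv[keep]
    dist2 = (du ** 2 + dv ** 2) / dist_crit ** 2

    interp = RegularGridInterpolator((u, v), ev, bounds_error=False,
                                     fill_value=np.nan)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pu, pv = uu.ravel(), vv.ravel()
    best = np.full(pu.size, np.inf)
    for o in range(du.size):
        q = np.stack([pu + du[o], pv + dv[o]], axis=1)
        dq = interp(q)
        g2 = (dq - ref.ravel()) ** 2 / dose_crit ** 2 + dist2[o]
        g2 = np.where(np.isnan(dq), np.inf, g2)
        best = np.minimum(best, g2)
    return np.sqrt(best).reshape(ref.shape)


def gamma_index(reference: ImageVolume, evaluated: ImageVolume,
                dose_criterion: float = 2.0, distance_criterion: float = 1.0,
                roi: PlaneROI | None = None,
                subgrid_divisions: int = 10,
                search_factor: float = 3.0) -> GammaResult:
    """Global-normalization gamma between two co-registered dose grids.

    With ``roi`` given, the analysis is 2D on that plane (the evaluated
    dose is interpolated in-plane); with ``roi=None`` a 3D analysis is run
    slice-by-slice perpendicular to y with in-plane search, which bounds
    the true 3D gamma from above.
    """
    if not reference.grid_matches(evaluated):
        raise GeometryError("dose grids do not match")
    if np.any(np.asarray(reference.spacing) > subgrid_divisions * distance_criterion):
        raise GeometryError(
            "grid spacing too coarse for the distance criterion; "
            "supply finer dose grids")

    if roi is not None:
        ref, u, v = _extract_plane(reference, roi)
        ev, _, _ = _extract_plane(evaluated, roi)
        gamma = _gamma_plane(ref, ev, u, v, dose_criterion, distance_criterion,
                             subgrid_divisions, search_factor)
    else:
        u = reference.origin[0] + reference.spacing[0] * np.arange(reference.shape[0])
        w = reference.origin[2] + reference.spacing[2] * np.arange(reference.shape[2])
        planes = []
        for j in range(reference.shape[1]):
            planes.append(_gamma_plane(
                reference.data[:, j, :], evaluated.data[:, j, :], u, w,
                dose_criterion, distance_criterion, subgrid_divisions,
                search_factor))
        gamma = np.stack(planes, axis=1)

    return GammaResult(
        gamma=gamma,
        mean=float(gamma.mean()),
        sigma=float(gamma.std()),
        max=float(gamma.max()),
        passing_rate=float(100.0 * (gamma <= 1.0).mean()),
        dose_criterion=dose_criterion,
        distance_criterion=distance_criterion,
    )
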