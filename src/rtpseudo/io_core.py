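"""Geometric image data model and NIfTI I/O.

All geometry lives in physical LPS millimeter space.  A volume is a 3D
array indexed ``data[i, j, k]`` together with voxel spacing, the physical
position of the first voxel center (origin) and a 3x3 orthonormal
direction-cosine matrix, so that

    physical = origin + direction @ (spacing * index)

with 0-based indices addressing voxel centers.

CT-like volumes that were resampled from a scan with limited coverage may
contain an *out-of-scan sentinel* (NaN) marking voxels the scanner never
saw; everything downstream must either handle or eliminate it explicitly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "SENTINEL",
    "is_sentinel",
    "FormatError",
    "GeometryError",
    "RegistrationError",
    "PlanningError",
    "ImageVolume",
    "BinaryMask",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

#: Out-of-scan sentinel written by resampling when a voxel maps outside the
#: source scan's physical extent.  A non-finite marker so it can never be
#: mistaken for a Hounsfield value.
SENTINEL = np.nan

_ORTHO_TOL = 1e-6


def is_sentinel(a: np.ndarray) -> np.ndarray:
    """Boolean map of out-of-scan voxels."""
    return np.isnan(a)


class FormatError(ValueError):
    """File content violates the expected image format or geometry contract."""


class GeometryError(ValueError):
    """Volume/mask/transform geometry is invalid or inconsistent."""


class RegistrationError(RuntimeError):
    """Rigid registration failed (no overlap, divergence, ...)."""


class PlanningError(RuntimeError):
    """Beam/plan construction could not satisfy its constraints."""


def _check_direction(direction: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    direction = np.asarray(direction, dtype=float)
    if direction.shape != (3, 3):
        raise GeometryError(f"direction must be 3x3, got {direction.shape}")
    if not np.allclose(direction.T @ direction, np.eye(3), atol=tol):
        raise GeometryError("direction matrix is not orthonormal")
    if np.linalg.det(direction) < 0:
        raise GeometryError("direction matrix has negative determinant (reflection)")
    return direction


@dataclass
class ImageVolume:
    """3D scalar grid with physical geometry.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz)``.  HU for CT-like volumes, arbitrary
        units for MR, percent of prescription for dose.
    spacing
        Voxel size in mm per axis; all components > 0.
    origin
        Physical (LPS, mm) position of the center of voxel ``(0, 0, 0)``.
    direction
        3x3 orthonormal direction-cosine matrix, determinant +1.
    modality
        One of ``CT``, ``MR``, ``DOSE``, ``MASK``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be 3 positive reals, got {self.spacing}")
        if self.origin.shape != (3,):
            raise GeometryError("origin must be a 3-vector (mm)")
        self.direction = _check_direction(self.direction)
        if self.modality not in ("CT", "MR", "DOSE", "MASK"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(np.isinf(self.data)):
            raise FormatError("volume contains infinite values")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (..., 3) 0-based voxel indices to physical mm coordinates."""
        index = np.asarray(index, dtype=float)
        return self.origin + (index * self.spacing) @ self.direction.T

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) physical mm points to continuous voxel indices."""
        points = np.asarray(points, dtype=float)
        return ((points - self.origin) @ self.direction) / self.spacing

    def grid_matches(self, other: "ImageVolume | BinaryMask", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "ImageVolume":
        """New volume on the same grid carrying different voxel data."""
        return ImageVolume(
            data=data,
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            direction=self.direction.copy(),
            modality=modality or self.modality,
        )

    def copy(self) -> "ImageVolume":
        return self.with_data(self.data.copy())


@dataclass
class BinaryMask:
    """Binary structure indicator sharing an ImageVolume geometry contract."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D mask, got ndim={self.data.ndim}")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError(f"mask values must be in {{0,1}}, found {vals[:10]}")
        self.data = self.data.astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be 3 positive reals, got {self.spacing}")
        self.direction = _check_direction(self.direction)

    @classmethod
    def from_volume(cls, vol: ImageVolume, data: np.ndarray) -> "BinaryMask":
        return cls(data=data, spacing=vol.spacing.copy(), origin=vol.origin.copy(),
                   direction=vol.direction.copy())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def volume_cc(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_cc

    def grid_matches(self, other, tol: float = 1e-6) -> bool:
        return ImageVolume.grid_matches(self, other, tol)  # type: ignore[arg-type]

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        return ImageVolume.index_to_physical(self, index)  # type: ignore[arg-type]

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        return ImageVolume.physical_to_index(self, points)  # type: ignore[arg-type]

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.data.astype(np.uint8), self.spacing.copy(),
                           self.origin.copy(), self.direction.copy(), modality="MASK")


@dataclass
class RigidTransform:
    """6-DOF rigid map: physical points of the moving space -> fixed space.

    ``p_fixed = rotation @ p_moving + translation`` (mm).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthonormal (tol 1e-8)")
        if np.linalg.det(self.rotation) < 0:
            raise GeometryError("rotation determinant must be +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler(cls, angles_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation from extrinsic x-y-z Euler angles in degrees."""
        ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(rz @ ry @ rx, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise GeometryError("expected a 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation (angle of the axis-angle form), degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_sitk(self) -> sitk.AffineTransform:
        """As a SimpleITK transform mapping moving-space points to fixed space."""
        t = sitk.AffineTransform(3)
        t.SetMatrix(self.rotation.ravel().tolist())
        t.SetTranslation(self.translation.tolist())
        return t


# -- SimpleITK bridge -----------------------------------------------------
# SimpleITK images are indexed (x, y, z) through the API but their numpy
# views are (z, y, x); the transposes below keep our (i, j, k) = (x, y, z)
# array convention.

def to_sitk(vol: ImageVolume | BinaryMask) -> sitk.Image:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(np.asarray(vol.direction, dtype=float).ravel()))
    return img


def from_sitk(img: sitk.Image, modality: str = "CT") -> ImageVolume:
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3D image, got {img.GetDimension()}D")
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    try:
        direction = _check_direction(direction)
    except GeometryError as exc:
        raise FormatError(f"image direction is not a proper rotation: {exc}") from exc
    return ImageVolume(
        data=data,
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=np.asarray(img.GetOrigin(), dtype=float),
        direction=direction,
        modality=modality,
    )


# -- file I/O -------------------------------------------------------------

def read_volume(path: str | Path, modality: str = "CT") -> ImageVolume:
    """Read a NIfTI volume; geometry reproduces the file's affine.

    Raises ``FileNotFoundError`` for a missing file and ``FormatError`` for a
    non-3D image or a non-orthonormal affine.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - backend-specific message
        raise FormatError(f"could not read {path}: {exc}") from exc
    return from_sitk(img, modality=modality)


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii or .nii.gz)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    sitk.WriteImage(to_sitk(vol), str(path))
    return path


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path, modality="MASK")
    return BinaryMask(vol.data, vol.spacing, vol.origin, vol.direction)


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    return write_volume(mask.as_volume(), path)
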