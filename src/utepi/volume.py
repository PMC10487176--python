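"""3-D image containers, NIfTI I/O, world-space affine transforms and resampling.

The whole package works in a single world coordinate frame measured in
millimetres.  A :class:`VoxelGrid` stores a scalar volume together with its
geometry; voxel indices are 0-based, voxel-centre based, and ordered
``(i, j, k)`` with ``i`` the fastest-varying index along world ``x``.  The
world position of voxel ``(i, j, k)`` is::

    world = origin + direction @ (i * s_x, j * s_y, k * s_z)

:class:`AffineTransform` is a plain world-to-world affine ``x -> M x + t``.
Resampling follows the *pull* convention used by ITK: the output value at a
reference-grid point ``x`` is the moving image sampled at ``T(x)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "VoxelGrid",
    "BoneMask",
    "AffineTransform",
    "read_volume",
    "write_volume",
    "resample",
]

_ORTHO_TOL = 1e-3


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise ValueError(f"{name} must be a 3-vector, got shape {np.shape(x)}")
    return v


@dataclass
class VoxelGrid:
    """A 3-D scalar image with spacing/origin/direction metadata (mm)."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype.kind in "iub":
            self.values = self.values.astype(np.float64)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3-D array")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if not np.all(self.spacing > 0):
            raise ValueError("all spacing components must be strictly positive")
        self.origin = _as_vec3(self.origin, "origin")
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction.T @ self.direction, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("direction matrix must be orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        """New grid sharing this geometry with different voxel values."""
        if np.shape(values)[:3] != self.shape:
            raise ValueError("values shape does not match grid shape")
        return VoxelGrid(np.asarray(values), self.spacing.copy(),
                         self.origin.copy(), self.direction.copy())

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return self.origin + (self.direction * self.spacing) @ idx

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense world-coordinate arrays (X, Y, Z), each of ``self.shape``."""
        ii, jj, kk = np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")
        A = self.direction * self.spacing
        pts = (A[:, 0, None, None, None] * ii
               + A[:, 1, None, None, None] * jj
               + A[:, 2, None, None, None] * kk
               + self.origin[:, None, None, None])
        return pts[0], pts[1], pts[2]

    def center(self) -> np.ndarray:
        """World coordinates of the geometric centre of the grid."""
        return self.index_to_world((np.asarray(self.shape) - 1) / 2.0)

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.direction, other.direction, atol=tol))


@dataclass
class BoneMask(VoxelGrid):
    """Boolean volume on a :class:`VoxelGrid` geometry."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.values = self.values.astype(bool)
        vals = self.values
        super().__post_init__()
        self.values = vals  # keep boolean payload; geometry checks done above

    @property
    def count(self) -> int:
        """Exact number of foreground voxels."""
        return int(np.count_nonzero(self.values))

    def with_values(self, values: np.ndarray) -> "BoneMask":
        if np.shape(values)[:3] != self.shape:
            raise ValueError("values shape does not match grid shape")
        return BoneMask(np.asarray(values), self.spacing.copy(),
                        self.origin.copy(), self.direction.copy())

    @classmethod
    def like(cls, grid: VoxelGrid, values: np.ndarray) -> "BoneMask":
        return cls(values, grid.spacing.copy(), grid.origin.copy(),
                   grid.direction.copy())


@dataclass
class AffineTransform:
    """World-space affine map ``x -> matrix @ x + translation`` (mm)."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = _as_vec3(self.translation, "translation")
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("transform matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        return cls(np.eye(3), t)

    @classmethod
    def rotation(cls, axis: int, degrees: float, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        """Rotation about one world axis (0=x, 1=y, 2=z) through ``center``."""
        c, s = np.cos(np.deg2rad(degrees)), np.sin(np.deg2rad(degrees))
        R = np.eye(3)
        a, b = [(1, 2), (0, 2), (0, 1)][axis]
        R[a, a] = c
        R[b, b] = c
        R[a, b] = -s if axis != 1 else s
        R[b, a] = s if axis != 1 else -s
        center = _as_vec3(center, "center")
        return cls(R, center - R @ center)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points of shape (..., 3) through the affine."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix,
                               self.matrix @ other.translation + self.translation)

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def as_matrix4(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.matrix
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix4(cls, m: np.ndarray) -> "AffineTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def save(self, path) -> None:
        """Write as a plain-text 4x4 row-major matrix."""
        np.savetxt(path, self.as_matrix4(), fmt="%.17g")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls.from_matrix4(np.loadtxt(path))


# ---------------------------------------------------------------------------
# File I/O

def write_volume(grid: VoxelGrid, path) -> None:
    """Write a grid as NIfTI-1 (.nii / .nii.gz); float payloads are lossless."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = np.eye(4)
    affine[:3, :3] = grid.direction * grid.spacing
    affine[:3, 3] = grid.origin
    data = np.asarray(grid.values)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_sform(affine, code=1)
    img.header.set_qform(affine, code=1)
    nib.save(img, str(path))


def read_volume(path) -> VoxelGrid:
    """Read a NIfTI file (or a directory of DICOM slices) into a VoxelGrid.

    Integer stored types are promoted to float64.  Files whose direction
    matrix is not orthonormal are rejected with a diagnostic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        return _read_dicom_dir(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types for bad formats
        raise ValueError(f"unsupported volume format: {path}") from exc
    affine = img.affine
    A = affine[:3, :3]
    spacing = np.linalg.norm(A, axis=0)
    if np.any(spacing <= 0):
        raise ValueError(f"non-positive voxel spacing in {path}")
    direction = A / spacing
    if not np.allclose(direction.T @ direction, np.eye(3), atol=_ORTHO_TOL):
        raise ValueError(f"non-orthonormal direction matrix in {path}")
    values = np.asarray(img.dataobj)
    if values.ndim != 3:
        values = np.squeeze(values)
    return VoxelGrid(values.astype(np.float64), spacing, affine[:3, 3], direction)


def _read_dicom_dir(path: Path) -> VoxelGrid:
    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(str(path))
    if not names:
        raise ValueError(f"no DICOM series found in {path}")
    reader.SetFileNames(names)
    return _from_sitk(reader.Execute())


# ---------------------------------------------------------------------------
# SimpleITK bridge and resampling

def _to_sitk(grid: VoxelGrid) -> sitk.Image:
    data = np.asarray(grid.values, dtype=np.float64)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    img.SetDirection(tuple(grid.direction.flatten()))
    return img


def _from_sitk(img: sitk.Image) -> VoxelGrid:
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    return VoxelGrid(values.astype(np.float64), np.asarray(img.GetSpacing()),
                     np.asarray(img.GetOrigin()), direction)


def _to_sitk_transform(t: AffineTransform) -> sitk.AffineTransform:
    st = sitk.AffineTransform(3)
    st.SetMatrix(tuple(t.matrix.flatten()))
    st.SetTranslation(tuple(t.translation))
    return st


def resample(moving: VoxelGrid, transform: AffineTransform | None,
             reference: VoxelGrid, interpolation: str = "linear",
             fill: float = 0.0) -> VoxelGrid:
    """Pull ``moving`` onto the geometry of ``reference``.

    The output value at reference world point ``x`` is ``moving`` sampled at
    ``transform(x)``; points mapping outside ``moving`` receive ``fill``.
    Use ``interpolation='nearest'`` for masks.
    """
    if transform is None:
        transform = AffineTransform.identity()
    interp = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}
    if interpolation not in interp:
        raise ValueError(f"unknown interpolation mode: {interpolation!r}")
    was_mask = np.asarray(moving.values).dtype == bool
    out = sitk.Resample(_to_sitk(moving), _to_sitk(reference),
                        _to_sitk_transform(transform), interp[interpolation],
                        float(fill), sitk.sitkFloat64)
    result = _from_sitk(out)
    result = reference.with_values(result.values)  # exact reference geometry
    if was_mask:
        return BoneMask.like(reference, result.values > 0.5)
    return result
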