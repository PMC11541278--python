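"""Core image-geometry types and voxel/world coordinate transforms.

All world coordinates are RAS+ millimeters. Voxel indices are 0-based and
refer to voxel centers; fractional indices are permitted everywhere so that
interpolated sampling and sub-voxel localization share one convention.
Orientation is stored explicitly as a 3x3 matrix of unit column vectors, and
anisotropic spacing is honored in every physical-space computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np

from .errors import FormatError, GeometryError

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids circular import
    from .reformat import PlaneFrame

_ORTHO_TOL = 1e-6


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


@dataclass(frozen=True, eq=False)
class VolumeGrid:
    """Regular 3D sampling grid embedded in world (RAS, mm) space.

    Parameters
    ----------
    shape
        Number of voxels along each axis (positive integers).
    spacing
        Voxel edge lengths in mm (positive).
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    orientation
        3x3 matrix whose *columns* are the unit world-direction vectors of
        the voxel axes. Must be orthonormal; violations raise
        :class:`GeometryError` and are never silently normalized.
    """

    shape: tuple[int, int, int]
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", _as_vec3(self.spacing))
        object.__setattr__(self, "origin", _as_vec3(self.origin))
        object.__setattr__(
            self, "orientation", np.asarray(self.orientation, dtype=float).reshape(3, 3)
        )
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise GeometryError(f"grid shape must be 3 positive integers, got {self.shape}")
        if not np.all(np.isfinite(self.spacing)) or np.any(self.spacing <= 0):
            raise GeometryError(f"spacing components must be positive, got {self.spacing}")
        gram = self.orientation.T @ self.orientation
        if not np.allclose(gram, np.eye(3), atol=_ORTHO_TOL):
            raise GeometryError(
                "orientation columns must be unit length and mutually orthogonal "
                f"(max deviation {np.abs(gram - np.eye(3)).max():.3g})"
            )

    def __eq__(self, other):
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return (self.shape == other.shape
                and np.array_equal(self.spacing, other.spacing)
                and np.array_equal(self.origin, other.origin)
                and np.array_equal(self.orientation, other.orientation))

    # ------------------------------------------------------------------ #
    @property
    def affine(self) -> np.ndarray:
        """4x4 homogeneous voxel-index -> world-mm matrix."""
        a = np.eye(4)
        a[:3, :3] = self.orientation * self.spacing[np.newaxis, :]
        a[:3, 3] = self.origin
        return a

    @property
    def physical_extent(self) -> np.ndarray:
        """Edge-to-edge extent (mm) between first and last voxel centers."""
        return (np.array(self.shape) - 1) * self.spacing

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_to_world(self, index) -> np.ndarray:
        """Map (fractional) voxel indices to world mm, voxel-center convention.

        Accepts a single triple or an ``(..., 3)`` array. Indices outside the
        grid are allowed; the extrapolated point is returned.
        """
        idx = np.asarray(index, dtype=float)
        return idx * self.spacing @ self.orientation.T + self.origin

    def world_to_voxel(self, point) -> np.ndarray:
        """Exact inverse of :meth:`voxel_to_world` (fractional indices)."""
        p = np.asarray(point, dtype=float)
        return (p - self.origin) @ self.orientation / self.spacing

    def contains_world(self, point, margin_mm: float = 0.0) -> bool:
        """True if ``point`` lies within the voxel-center bounding box."""
        idx = self.world_to_voxel(point)
        lo = margin_mm / self.spacing
        hi = np.array(self.shape) - 1 - lo
        return bool(np.all(idx >= lo) and np.all(idx <= hi))

    def boundary_distance_mm(self, point) -> float:
        """Distance (mm) from a world point to the nearest grid face,
        measured along the voxel axes. Negative values mean outside."""
        idx = self.world_to_voxel(point)
        d_lo = idx * self.spacing
        d_hi = (np.array(self.shape) - 1 - idx) * self.spacing
        return float(min(d_lo.min(), d_hi.min()))


def _check_array(grid: VolumeGrid, arr: np.ndarray, what: str) -> None:
    if tuple(arr.shape) != grid.shape:
        raise GeometryError(f"{what} shape {arr.shape} does not match grid shape {grid.shape}")


@dataclass
class Volume3D:
    """A scalar 3D image (arbitrary intensity units) on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        _check_array(self.grid, self.data, "intensity array")
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("volume intensities must all be finite")


@dataclass
class Mask3D:
    """Binary label field on a :class:`VolumeGrid` (1 = needle feature)."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise GeometryError(f"mask labels must be in {{0,1}}, found {uniq[:5]}")
        self.data = arr.astype(np.uint8)
        _check_array(self.grid, self.data, "label array")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def world_coordinates(self) -> np.ndarray:
        """World-mm coordinates of the centers of all mask voxels, (N, 3)."""
        idx = np.argwhere(self.data > 0)
        return self.grid.voxel_to_world(idx)


@dataclass
class Mask2D:
    """Binary label field on an oriented sampling plane (module reformat)."""

    frame: "PlaneFrame"
    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise GeometryError(f"mask labels must be in {{0,1}}, found {uniq[:5]}")
        self.data = arr.astype(np.uint8)
        if tuple(self.data.shape) != tuple(self.frame.size):
            raise GeometryError(
                f"2D mask shape {self.data.shape} does not match frame size {self.frame.size}"
            )

    @property
    def n_pixels(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------- #
# NIfTI-1 I/O
# ---------------------------------------------------------------------- #

def _grid_from_affine(affine: np.ndarray, shape, path) -> VolumeGrid:
    m = affine[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise GeometryError(f"{path}: affine implies non-positive voxel spacing {spacing}")
    orientation = m / spacing[np.newaxis, :]
    gram = orientation.T @ orientation
    if not np.allclose(gram, np.eye(3), atol=1e-4):
        raise GeometryError(f"{path}: non-orthogonal voxel axes in affine")
    return VolumeGrid(shape=tuple(shape), spacing=spacing, origin=affine[:3, 3],
                      orientation=orientation)


def _load_nifti(path):
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    pixdim = np.asarray(img.header["pixdim"][1:4], dtype=float)
    if np.any(pixdim <= 0) or not np.all(np.isfinite(pixdim)):
        raise GeometryError(f"{path}: header field 'pixdim' has non-positive spacing {pixdim}")
    if img.ndim != 3:
        raise FormatError(f"{path}: field 'dim' describes a {img.ndim}-D image, expected 3-D")
    grid = _grid_from_affine(img.affine, img.shape, path)
    return img, grid


def read_volume(path) -> Volume3D:
    """Read a 3D scalar volume from a NIfTI-1 file (.nii / .nii.gz)."""
    img, grid = _load_nifti(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: intensity data contains non-finite values")
    return Volume3D(grid=grid, data=data)


def write_volume(volume: Volume3D, path) -> None:
    """Write a volume as NIfTI-1 with the full RAS affine."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.grid.affine)
    nib.save(img, str(path))


def read_mask(path) -> Mask3D:
    """Read a binary mask volume ({0,1}, stored unsigned 8-bit)."""
    img, grid = _load_nifti(path)
    data = np.asarray(img.dataobj)
    return Mask3D(grid=grid, data=(data > 0.5).astype(np.uint8))


def write_mask(mask: Mask3D, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))
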