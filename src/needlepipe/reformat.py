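"""Oblique axial plane construction and 2D reformatting (pipeline Step 2).

Given the principal axis of the coarse 3D needle segmentation, this module
constructs the plane that contains the axis and whose normal is as close as
possible to the superior-inferior (axial) normal — the canonical "oblique
axial" plane — then resamples the source volume onto it. The
:class:`PlaneFrame` carries the exact plane-to-world affine used later to
lift 2D tip/entry coordinates back into 3D, so Step 2 and Step 3 share one
coordinate contract.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryError, SegmentationEmptyError
from .imgeom import Mask3D, Volume3D, VolumeGrid

log = logging.getLogger(__name__)

_TOL = 1e-9


@dataclass(frozen=True)
class PlaneFrame:
    """An oriented 2D sampling plane embedded in 3D world space.

    ``origin`` is the world position (mm) of the center of pixel (0, 0);
    ``u_axis`` is the in-plane needle-axis direction, ``v_axis`` the
    orthogonal in-plane direction, and ``normal = u x v`` (right-handed).
    Pixel (i, j) sits at ``origin + i*du*u + j*dv*v``.
    """

    origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    pixel_spacing: tuple[float, float]
    size: tuple[int, int]

    def __post_init__(self):
        for name in ("origin", "u_axis", "v_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        object.__setattr__(self, "pixel_spacing",
                           (float(self.pixel_spacing[0]), float(self.pixel_spacing[1])))
        object.__setattr__(self, "size", (int(self.size[0]), int(self.size[1])))
        u, v = self.u_axis, self.v_axis
        if abs(np.linalg.norm(u) - 1) > _TOL or abs(np.linalg.norm(v) - 1) > _TOL:
            raise GeometryError("plane axes must be unit length")
        if abs(np.dot(u, v)) > _TOL:
            raise GeometryError("plane axes must be orthogonal")
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0:
            raise GeometryError("pixel spacing must be positive")
        if self.size[0] < 1 or self.size[1] < 1:
            raise GeometryError("frame size must be at least 1x1")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u_axis, self.v_axis)

    # -- serialization ------------------------------------------------- #
    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "u_axis": self.u_axis.tolist(),
            "v_axis": self.v_axis.tolist(),
            "pixel_spacing": list(self.pixel_spacing),
            "size": list(self.size),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneFrame":
        return cls(origin=d["origin"], u_axis=d["u_axis"], v_axis=d["v_axis"],
                   pixel_spacing=tuple(d["pixel_spacing"]), size=tuple(d["size"]))


@dataclass
class Reformatted2D:
    """A 2D image resampled from a 3D volume on a :class:`PlaneFrame`.

    ``valid`` flags pixels whose sampling point lay inside the source
    volume; out-of-bounds pixels are filled with 0 and must not be treated
    as tissue by downstream segmentation.
    """

    frame: PlaneFrame
    intensities: np.ndarray
    valid: np.ndarray = field(default=None)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if tuple(self.intensities.shape) != tuple(self.frame.size):
            raise GeometryError(
                f"image shape {self.intensities.shape} != frame size {self.frame.size}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise GeometryError("reformatted intensities must be finite")
        if self.valid is None:
            self.valid = np.ones(self.frame.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)


# ---------------------------------------------------------------------- #
# plane construction
# ---------------------------------------------------------------------- #

def oblique_axial_normal(axis_direction: np.ndarray,
                         si_axis=(0.0, 0.0, 1.0),
                         ap_axis=(0.0, 1.0, 0.0)) -> tuple[np.ndarray, bool]:
    """Normal of the plane containing ``axis_direction`` that is closest to
    axial: the unit projection of the superior-inferior axis onto the
    subspace orthogonal to the needle axis.

    Returns ``(normal, used_fallback)``; when the needle is parallel to the
    S-I axis the anterior-posterior axis is projected instead.
    """
    u = np.asarray(axis_direction, dtype=float)
    z = np.asarray(si_axis, dtype=float)
    w = z - np.dot(z, u) * u
    fallback = False
    if np.linalg.norm(w) < 1e-6:
        fallback = True
        y = np.asarray(ap_axis, dtype=float)
        w = y - np.dot(y, u) * u
        log.warning("needle parallel to the S-I axis; oblique plane normal "
                    "falls back to the anterior-posterior axis")
        if np.linalg.norm(w) < 1e-6:  # pragma: no cover - u cannot align with both
            raise GeometryError("axis direction parallel to both S-I and A-P axes")
    return w / np.linalg.norm(w), fallback


def build_oblique_axial_frame(axis_point: np.ndarray, axis_direction: np.ndarray,
                              mask: Mask3D, margin_mm: float = 20.0,
                              pixel_spacing: tuple[float, float] = (1.35, 1.35)) -> PlaneFrame:
    """Construct the oblique axial reformatting plane through the needle axis.

    The plane contains the line ``(axis_point, axis_direction)``; among all
    such planes its normal maximizes alignment with the S-I axis. The frame
    origin and size are chosen so every mask voxel projects inside the frame
    with at least ``margin_mm`` margin, rounded up to even pixel counts.
    """
    u = np.asarray(axis_direction, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-6:
        raise GeometryError("axis_direction must be unit length")
    if mask.n_voxels == 0:
        raise SegmentationEmptyError("cannot build a reformatting frame from an empty mask")
    axis_point = np.asarray(axis_point, dtype=float)
    normal, _ = oblique_axial_normal(u)
    v = np.cross(normal, u)  # then cross(u, v) == normal: right-handed
    pts = mask.world_coordinates() - axis_point
    s, t = pts @ u, pts @ v
    du, dv = pixel_spacing
    s_lo, s_hi = s.min() - margin_mm, s.max() + margin_mm
    t_lo, t_hi = t.min() - margin_mm, t.max() + margin_mm
    nu = int(np.ceil((s_hi - s_lo) / du)) + 1
    nv = int(np.ceil((t_hi - t_lo) / dv)) + 1
    nu += nu % 2
    nv += nv % 2
    origin = axis_point + s_lo * u + t_lo * v
    return PlaneFrame(origin=origin, u_axis=u, v_axis=v,
                      pixel_spacing=(du, dv), size=(nu, nv))


# ---------------------------------------------------------------------- #
# resampling and coordinate maps
# ---------------------------------------------------------------------- #

def plane_to_world(p2, frame: PlaneFrame) -> np.ndarray:
    """Lift in-plane mm coordinates (s, t) to world mm."""
    p2 = np.asarray(p2, dtype=float)
    return frame.origin + p2[..., 0, np.newaxis] * frame.u_axis \
        + p2[..., 1, np.newaxis] * frame.v_axis


def world_to_plane(p3, frame: PlaneFrame) -> tuple[np.ndarray, np.ndarray]:
    """Project world mm points onto the plane.

    Returns ``((s, t), out_of_plane_distance_mm)``; the distance is signed
    along the frame normal.
    """
    rel = np.asarray(p3, dtype=float) - frame.origin
    s = rel @ frame.u_axis
    t = rel @ frame.v_axis
    d = rel @ frame.normal
    return np.stack([s, t], axis=-1), d


def pixel_to_plane_mm(indices, frame: PlaneFrame) -> np.ndarray:
    """Convert (i, j) pixel indices to in-plane (s, t) mm coordinates."""
    idx = np.asarray(indices, dtype=float)
    return idx * np.asarray(frame.pixel_spacing)


def resample_plane(volume: Volume3D, frame: PlaneFrame,
                   interpolation: str = "linear") -> Reformatted2D:
    """Resample a volume onto a plane frame.

    ``interpolation`` is ``linear`` or ``nearest`` (nearest preserves
    binarity of label volumes). Sampling points outside the volume are
    filled with 0 and flagged invalid.
    """
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    nu, nv = frame.size
    ii, jj = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    pts_plane = np.stack([ii * frame.pixel_spacing[0], jj * frame.pixel_spacing[1]], axis=-1)
    world = plane_to_world(pts_plane.reshape(-1, 2), frame)
    vox = volume.grid.world_to_voxel(world)
    shape = np.array(volume.grid.shape)
    valid = np.all((vox >= 0) & (vox <= shape - 1), axis=1).reshape(nu, nv)
    samples = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=np.float32), vox.T, order=order,
        mode="constant", cval=0.0,
    ).reshape(nu, nv)
    samples[~valid] = 0.0
    return Reformatted2D(frame=frame, intensities=samples, valid=valid)


def reformatted_to_volume(image: Reformatted2D, thickness_mm: float = 1.0) -> Volume3D:
    """Embed a reformatted image as a single-slice 3D volume with the full
    oblique affine, so external viewers can confirm the geometry."""
    f = image.frame
    grid = VolumeGrid(
        shape=(f.size[0], f.size[1], 1),
        spacing=(f.pixel_spacing[0], f.pixel_spacing[1], thickness_mm),
        origin=f.origin,
        orientation=np.stack([f.u_axis, f.v_axis, f.normal], axis=1),
    )
    return Volume3D(grid=grid, data=image.intensities[:, :, np.newaxis])
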