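"""Seeded synthetic MR phantom generator with needle signal-void features.

A phantom emulates a 3D T1-weighted GRE Dixon water volume containing the
dark elongated artifact that a metallic needle induces through susceptibility
effects. The background is a smooth positive texture (low-frequency Gaussian
random field) plus optional white Gaussian noise; needle voxels are darkened
multiplicatively. The generator returns the exact voxel set it darkened as
the ground-truth mask, together with the true tip, entry point and axis, so
that the localization pipeline can be validated by parameter recovery.

The needle feature is modeled as a cylinder of radius ``needle_radius`` with
flat end caps at the entry and tip, optionally augmented by a spherical
"bloom" of radius ``tip_bloom_radius`` centered at the tip (susceptibility
blooming enlarges the artifact near the tip on real images; with a nonzero
bloom the feature extremity deliberately overshoots the true tip).

The insertion angle convention follows interventional usage: the angle is
measured between the needle and the axial plane (elevation), so 0 deg is a
horizontal in-plane insertion and -90 deg points straight inferior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import GeometryError, PlacementError
from .imgeom import Mask3D, Volume3D, VolumeGrid

log = logging.getLogger(__name__)

#: Acquisition grid of the 3D confirmation scans this generator emulates:
#: 176 x 256 in-plane matrix at 1.35 x 1.35 mm^2, 120 slices of 1.5 mm.
TABLE1_SHAPE = (176, 256, 120)
TABLE1_SPACING = (1.35, 1.35, 1.5)


def default_grid() -> VolumeGrid:
    """Full acquisition-size grid (176 x 256 x 120 @ 1.35 x 1.35 x 1.5 mm)."""
    return VolumeGrid(shape=TABLE1_SHAPE, spacing=TABLE1_SPACING, origin=(0.0, 0.0, 0.0))


def small_grid() -> VolumeGrid:
    """Quarter-volume preset (88 x 128 x 60) at native spacing, for fast tests."""
    return VolumeGrid(shape=(88, 128, 60), spacing=TABLE1_SPACING, origin=(0.0, 0.0, 0.0))


def direction_from_angles(angle_to_axial_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit insertion direction from elevation/azimuth angles.

    ``angle_to_axial_deg`` is the angle between the needle and the axial
    (x-y) plane; ``azimuth_deg`` rotates within the axial plane from +x.
    """
    th = np.deg2rad(angle_to_axial_deg)
    ph = np.deg2rad(azimuth_deg)
    return np.array([np.cos(th) * np.cos(ph), np.cos(th) * np.sin(ph), np.sin(th)])


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic needle phantom.

    Intensity units are arbitrary; lengths in mm, angles in degrees.
    ``void_contrast`` is the fraction by which needle voxels are darkened
    (0.8 leaves them at 20% of the local background).
    """

    grid: VolumeGrid = field(default_factory=default_grid)
    entry_point: tuple[float, float, float] = (30.0, 30.0, 90.0)
    insertion_depth: float = 60.0
    angle_to_axial_deg: float = -20.0
    azimuth_deg: float = 30.0
    needle_radius: float = 2.5
    tip_bloom_radius: float = 0.0
    background_mean: float = 100.0
    background_texture_scale: float = 2.5
    background_texture_sd: float = 3.0
    noise_sd: float = 5.0
    void_contrast: float = 0.8
    n_distractors: int = 0
    distractor_max_volume_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.insertion_depth <= 0:
            raise GeometryError("insertion_depth must be positive")
        if self.needle_radius <= 0:
            raise GeometryError("needle_radius must be positive")
        if not 0 < self.void_contrast <= 1:
            raise GeometryError("void_contrast must lie in (0, 1]")
        if self.tip_bloom_radius < 0:
            raise GeometryError("tip_bloom_radius must be >= 0")
        if not 0 <= self.distractor_max_volume_fraction < 1:
            raise GeometryError("distractor_max_volume_fraction must lie in [0, 1)")
        if self.n_distractors < 0:
            raise GeometryError("n_distractors must be >= 0")

    @property
    def direction(self) -> np.ndarray:
        return direction_from_angles(self.angle_to_axial_deg, self.azimuth_deg)

    @property
    def entry(self) -> np.ndarray:
        return np.asarray(self.entry_point, dtype=float)

    @property
    def tip(self) -> np.ndarray:
        return self.entry + self.insertion_depth * self.direction


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth annotation of a generated phantom."""

    tip: np.ndarray
    entry: np.ndarray
    axis_direction: np.ndarray
    mask: Mask3D

    def __post_init__(self):
        object.__setattr__(self, "tip", np.asarray(self.tip, dtype=float))
        object.__setattr__(self, "entry", np.asarray(self.entry, dtype=float))
        d = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise GeometryError("axis_direction must be unit length")
        object.__setattr__(self, "axis_direction", d)


# ---------------------------------------------------------------------- #
# generation
# ---------------------------------------------------------------------- #

def _needle_voxel_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean needle-feature mask on the spec grid.

    A voxel belongs to the feature iff its center lies in the flat-capped
    cylinder {0 <= (p - entry).u <= depth, radial distance <= r} or within
    tip_bloom_radius of the tip. Evaluated only inside a bounding box around
    the needle for speed.
    """
    grid = spec.grid
    entry, tip, u = spec.entry, spec.tip, spec.direction
    pad = spec.needle_radius + spec.tip_bloom_radius + 2 * float(grid.spacing.max())
    # world AABB of the capsule, mapped to index space via the 8 corners
    lo_w = np.minimum(entry, tip) - pad
    hi_w = np.maximum(entry, tip) + pad
    corners = np.array([[lo_w[k] if b & (1 << k) == 0 else hi_w[k] for k in range(3)]
                        for b in range(8)])
    idx = grid.world_to_voxel(corners)
    lo = np.maximum(np.floor(idx.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(idx.max(axis=0)).astype(int), np.array(grid.shape) - 1)
    if np.any(lo > hi):
        return np.zeros(grid.shape, dtype=bool)
    ii, jj, kk = np.meshgrid(*(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij")
    pts = grid.voxel_to_world(np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
    rel = pts - entry
    a = rel @ u
    radial2 = np.einsum("ij,ij->i", rel, rel) - a * a
    inside = (a >= 0) & (a <= spec.insertion_depth) & (radial2 <= spec.needle_radius**2)
    if spec.tip_bloom_radius > 0:
        dt = pts - tip
        inside |= np.einsum("ij,ij->i", dt, dt) <= spec.tip_bloom_radius**2
    sub = inside.reshape(ii.shape)
    out = np.zeros(grid.shape, dtype=bool)
    out[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = sub
    return out


def _background_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive texture: Gaussian random field with correlation
    length ``background_texture_scale`` mm, renormalized to
    ``background_texture_sd`` around ``background_mean``."""
    white = rng.standard_normal(spec.grid.shape).astype(np.float32)
    if spec.background_texture_sd > 0 and spec.background_texture_scale > 0:
        sigma_vox = spec.background_texture_scale / spec.grid.spacing
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
        sd = smooth.std()
        if sd > 0:
            smooth *= spec.background_texture_sd / sd
        return spec.background_mean + smooth
    return np.full(spec.grid.shape, spec.background_mean, dtype=np.float32)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, TruthRecord]:
    """Generate one phantom volume and its ground truth, reproducibly.

    Raises :class:`GeometryError` if the needle leaves the grid or the
    insertion is too short for the axis to be recoverable
    (depth < 2 * max spacing).
    """
    grid = spec.grid
    if spec.insertion_depth < 2 * float(grid.spacing.max()):
        raise GeometryError(
            f"insertion depth {spec.insertion_depth} mm < 2 voxels: axis unrecoverable"
        )
    for name, p in (("entry", spec.entry), ("tip", spec.tip)):
        if not grid.contains_world(p):
            raise GeometryError(f"needle {name} point {p} lies outside the grid")

    rng = np.random.default_rng(spec.seed)
    vol = _background_field(spec, rng)
    mask = _needle_voxel_mask(spec)
    vol[mask] *= 1.0 - spec.void_contrast
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=grid.shape).astype(np.float32)
    truth = TruthRecord(
        tip=spec.tip, entry=spec.entry, axis_direction=spec.direction,
        mask=Mask3D(grid=grid, data=mask.astype(np.uint8)),
    )
    return Volume3D(grid=grid, data=vol), truth


# ---------------------------------------------------------------------- #
# distractors
# ---------------------------------------------------------------------- #

def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def add_distractors(volume: Volume3D, truth: TruthRecord, spec: PhantomSpec,
                    max_retries: int = 200) -> Volume3D:
    """Darken ``spec.n_distractors`` ellipsoidal blobs emulating other
    signal-void regions in the body.

    Each blob is strictly disjoint from the needle feature (placed with a
    physical safety gap) and strictly smaller than the needle component by
    voxel volume, so largest-component false-positive removal provably
    recovers the needle. Returns a new volume; ``n_distractors == 0`` returns
    the input unchanged.
    """
    if spec.n_distractors == 0:
        return volume
    grid = volume.grid
    rng = np.random.default_rng([spec.seed, 7919])
    needle_voxels = truth.mask.n_voxels
    vol = volume.data.copy()
    placed: list[tuple[np.ndarray, float]] = []  # (center, max semi-axis)
    extent = grid.physical_extent
    gap = 4.0
    if np.any(extent <= 20.0):
        raise PlacementError("grid too small to place distractors away from its faces")
    # keep distractors clear of the oblique reformatting plane through the
    # needle axis, so they emulate separate susceptibility regions elsewhere
    # in the body without ever entering the planar refinement stage's input
    from .reformat import oblique_axial_normal
    plane_normal, _ = oblique_axial_normal(truth.axis_direction)
    plane_clearance = 8.0

    vox_limit = spec.distractor_max_volume_fraction * needle_voxels
    for _ in range(spec.n_distractors):
        for attempt in range(max_retries):
            center_grid = rng.uniform(10.0, extent - 10.0)
            center = grid.origin + grid.orientation @ center_grid
            off_plane = abs(float((center - truth.entry) @ plane_normal))
            # size blobs relative to the needle so they are comparable
            # confounders yet provably smaller than the needle component
            target_mm3 = rng.uniform(0.3, 0.8) * vox_limit * grid.voxel_volume_mm3
            aniso = rng.uniform(0.6, 1.6, size=3)
            semi = (3.0 * target_mm3 / (4.0 * np.pi * np.prod(aniso))) ** (1 / 3) * aniso
            if (_point_segment_distance(center, truth.entry, truth.tip)
                    < semi.max() + spec.needle_radius + spec.tip_bloom_radius + gap):
                continue
            if off_plane < semi.max() + plane_clearance:
                continue
            if any(np.linalg.norm(center - c) < semi.max() + s + gap for c, s in placed):
                continue
            blob = _ellipsoid_mask(grid, center, semi)
            count = int(blob.sum())
            if count == 0 or count >= vox_limit:
                continue
            vol[blob] *= 1.0 - spec.void_contrast
            placed.append((center, float(semi.max())))
            break
        else:
            raise PlacementError(
                f"could not place distractor {len(placed) + 1} after {max_retries} retries"
            )
    return Volume3D(grid=grid, data=vol)


def _ellipsoid_mask(grid: VolumeGrid, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    lo_w, hi_w = center - semi.max(), center + semi.max()
    corners = np.array([[lo_w[k] if b & (1 << k) == 0 else hi_w[k] for k in range(3)]
                        for b in range(8)])
    idx = grid.world_to_voxel(corners)
    lo = np.maximum(np.floor(idx.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(idx.max(axis=0)).astype(int), np.array(grid.shape) - 1)
    out = np.zeros(grid.shape, dtype=bool)
    if np.any(lo > hi):
        return out
    ii, jj, kk = np.meshgrid(*(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij")
    pts = grid.voxel_to_world(np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
    q = (pts - center) / semi
    inside = np.einsum("ij,ij->i", q, q) <= 1.0
    out[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = inside.reshape(ii.shape)
    return out


# ---------------------------------------------------------------------- #
# sampling of study conditions
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class SpecRanges:
    """Sampling ranges for phantom generation.

    Defaults reproduce the insertion conditions observed in vivo:
    depth 1.94-12.26 cm and needle-to-axial-plane angle -87.64 to 2.23 deg.
    """

    depth_mm: tuple[float, float] = (19.4, 122.6)
    angle_to_axial_deg: tuple[float, float] = (-87.64, 2.23)
    azimuth_deg: tuple[float, float] = (0.0, 360.0)
    entry_face_depth_mm: tuple[float, float] = (3.0, 10.0)

    def __post_init__(self):
        for name in ("depth_mm", "angle_to_axial_deg", "azimuth_deg", "entry_face_depth_mm"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise GeometryError(f"range {name} is empty or inverted: ({lo}, {hi})")
        if self.depth_mm[0] <= 0:
            raise GeometryError("depth range must be positive")


_FACE_NORMALS = np.vstack([np.eye(3), -np.eye(3)])  # inward normals: +k faces at 0, -k at extent


def sample_spec(ranges: SpecRanges | None = None, n: int = 1, seed: int = 0,
                grid: VolumeGrid | None = None, *, tip_face_margin_mm: float = 20.0,
                **spec_overrides) -> list[PhantomSpec]:
    """Sample ``n`` phantom specs uniformly over the given insertion ranges.

    The entry point is placed a few mm inside the grid face that the
    insertion direction points away from (emulating a skin entry), with the
    tip kept at least ``tip_face_margin_mm`` from every face so that the
    boundary-proximity tip/entry rule is well posed. Deterministic for a
    fixed seed. Extra keyword arguments override :class:`PhantomSpec` fields
    (noise level, contrast, ...).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or SpecRanges()
    grid = grid or default_grid()
    extent = grid.physical_extent
    children = np.random.SeedSequence(seed).spawn(n)
    specs = []
    for child in children:
        rng = np.random.default_rng(child)
        for attempt in range(1000):
            depth = rng.uniform(*ranges.depth_mm)
            theta = rng.uniform(*ranges.angle_to_axial_deg)
            phi = rng.uniform(*ranges.azimuth_deg)
            d = direction_from_angles(theta, phi)
            d_grid = grid.orientation.T @ d
            face = int(np.argmax(_FACE_NORMALS @ d_grid))
            axis, inward = face % 3, 1.0 if face < 3 else -1.0
            face_depth = rng.uniform(*ranges.entry_face_depth_mm)
            entry_grid = rng.uniform(15.0, extent - 15.0)
            entry_grid[axis] = face_depth if inward > 0 else extent[axis] - face_depth
            tip_grid = entry_grid + depth * d_grid
            if np.any(tip_grid < tip_face_margin_mm) or np.any(
                    tip_grid > extent - tip_face_margin_mm):
                continue
            entry_world = grid.origin + grid.orientation @ entry_grid
            specs.append(PhantomSpec(
                grid=grid, entry_point=tuple(entry_world), insertion_depth=float(depth),
                angle_to_axial_deg=float(theta), azimuth_deg=float(phi),
                seed=int(rng.integers(2**31)), **spec_overrides,
            ))
            break
        else:
            raise PlacementError(
                "could not place a needle satisfying the face margins; "
                "reduce the depth range or use a larger grid"
            )
    return specs
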