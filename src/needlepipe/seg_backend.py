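"""Segmentation backends, false-positive removal and principal-axis estimation.

The pipeline treats segmentation as a pluggable contract with two roles: a
*volumetric* backend produces the coarse 3D needle-feature mask (Step 1) and
a *planar* backend refines it on the reformatted 2D image (Step 3). The
repository ships deterministic classical backends (intensity thresholding +
morphology) as the default so the geometric pipeline is fully testable
without trained weights; neural backends (e.g. transformer-based encoders)
plug in behind the same contract via :func:`train_backend` when an optional
neural runtime is installed.

Post-processing follows the needle-intervention assumption that the needle
signal void is the largest dark object: :func:`remove_false_positives`
keeps only the largest connected component. Components use 26-connectivity
in 3D (8 in 2D); oblique thin structures fragment under face-connectivity.
"""

from __future__ import annotations

import importlib.util
import logging
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import (AxisAmbiguousError, CapabilityError, DegenerateMaskError,
                     SegmentationEmptyError)
from .imgeom import Mask2D, Mask3D, Volume3D
from .reformat import Reformatted2D

log = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@runtime_checkable
class SegmentationBackend(Protocol):
    """Contract every segmentation backend satisfies.

    ``kind`` is ``"volumetric"`` (Volume3D -> Mask3D) or ``"planar"``
    (Reformatted2D -> Mask2D); the output mask must share the input's grid
    or frame exactly and be binary. ``descriptor`` is free-text provenance.
    """

    kind: str
    descriptor: str

    def predict(self, image): ...


# ---------------------------------------------------------------------- #
# classical reference backends
# ---------------------------------------------------------------------- #

def _physical_ball(radius_mm: float, spacing) -> np.ndarray | None:
    """Binary structuring element approximating a ball of physical radius."""
    spacing = np.asarray(spacing, dtype=float)
    r_vox = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    if np.all(r_vox == 0):
        return None
    grids = np.meshgrid(*(np.arange(-r, r + 1) for r in r_vox), indexing="ij")
    d2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return d2 <= radius_mm**2


#: Upper bound on the physical volume of a needle signal-void feature
#: (radius 2.5 mm at the deepest clinical insertion, ~13 cm), used to scale
#: the default threshold percentile to the grid.
MAX_FEATURE_VOLUME_MM3 = 2600.0


@dataclass(frozen=True)
class SegParams3D:
    """Classical 3D segmenter parameters.

    ``percentile_threshold`` is the intensity percentile (percent of all
    voxels) below which voxels are candidate needle feature. The percentile
    must exceed the feature's voxel fraction (else the cut lands inside the
    needle) while staying deep in the dark background tail; since that
    fraction depends on the grid, the default ``None`` auto-scales it to
    1.5x the largest expected feature fraction for the volume being
    segmented. Morphological opening (physical radius, optional) and the
    component-size floor remove noise speckle and background texture dips;
    size filtering alone suffices at moderate noise, and opening erodes a
    feature only ~2 voxels thick, so opening is off by default.
    """

    percentile_threshold: float | None = None
    min_component_voxels: int = 100
    opening_radius_mm: float = 0.0

    def resolve_percentile(self, grid) -> float:
        if self.percentile_threshold is not None:
            return self.percentile_threshold
        n_vox = float(np.prod(grid.shape))
        frac = MAX_FEATURE_VOLUME_MM3 / grid.voxel_volume_mm3 / n_vox
        return min(100.0 * 1.5 * frac, 5.0)


def _refine_threshold_to_gap(values: np.ndarray, thr: float,
                             min_gap_fraction: float = 0.25) -> float:
    """Move a tail threshold into the widest empty intensity gap below it.

    A signal void sits far below the background's dark tail, leaving a wide
    empty band between the two populations. Splitting at the midpoint of
    that band (when it spans at least ``min_gap_fraction`` of the sub-threshold
    intensity range) makes the cut insensitive to small quantile shifts, so
    adding or removing a few dark voxels elsewhere in the volume cannot flip
    borderline background voxels. With no clear bimodal gap the percentile
    threshold is returned unchanged.
    """
    v = np.sort(np.unique(values))
    if v.size < 2:
        return thr
    edges = np.append(v, thr)
    gaps = np.diff(edges)
    k = int(np.argmax(gaps))
    span = thr - v[0]
    if span <= 0 or gaps[k] < min_gap_fraction * span:
        return thr
    return float(edges[k] + 0.5 * gaps[k])


def segment_reference(volume: Volume3D, params: SegParams3D | None = None) -> Mask3D:
    """Deterministic classical 3D needle-feature segmentation.

    Voxels strictly darker than the ``percentile_threshold`` percentile of
    the volume are kept (with the cut refined into the bimodal intensity
    gap when one exists), opened with a physical-radius ball, and components
    below ``min_component_voxels`` are dropped. Raises
    :class:`SegmentationEmptyError` if nothing remains.
    """
    params = params or SegParams3D()
    data = np.asarray(volume.data)
    thr = np.percentile(data, params.resolve_percentile(volume.grid))
    tail = data[data < thr]
    if tail.size:
        thr = _refine_threshold_to_gap(tail, float(thr))
    cand = data < thr
    ball = _physical_ball(params.opening_radius_mm, volume.grid.spacing)
    if ball is not None and cand.any():
        cand = ndimage.binary_opening(cand, structure=ball)
    if cand.any() and params.min_component_voxels > 1:
        labels, n = ndimage.label(cand, structure=_STRUCT_26)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = np.flatnonzero(counts >= params.min_component_voxels)
        cand = np.isin(labels, keep)
    if not cand.any():
        raise SegmentationEmptyError("classical 3D segmentation produced an empty mask")
    return Mask3D(grid=volume.grid, data=cand.astype(np.uint8))


@dataclass(frozen=True)
class SegParams2D:
    """Classical 2D segmenter parameters (Otsu threshold on valid pixels)."""

    opening_radius_mm: float = 0.0
    min_component_pixels: int = 10
    keep_largest: bool = True


@dataclass
class ClassicalVolumetricBackend:
    """Default Step-1 backend: classical thresholding (see
    :func:`segment_reference`)."""

    params: SegParams3D = None
    kind: str = "volumetric"
    descriptor: str = "classical-threshold-3d"

    def __post_init__(self):
        self.params = self.params or SegParams3D()

    def predict(self, volume: Volume3D) -> Mask3D:
        return segment_reference(volume, self.params)


@dataclass
class ClassicalPlanarBackend:
    """Default Step-3 backend: Otsu thresholding of the reformatted image.

    The needle void and background are strongly bimodal on the reformatted
    plane, so Otsu's threshold separates them robustly across insertion
    depths. Out-of-volume padding is excluded from the threshold computation
    and forced to background.
    """

    params: SegParams2D = None
    kind: str = "planar"
    descriptor: str = "classical-otsu-2d"

    def __post_init__(self):
        self.params = self.params or SegParams2D()

    def predict(self, image: Reformatted2D) -> Mask2D:
        vals = image.intensities[image.valid]
        if vals.size == 0 or np.ptp(vals) == 0:
            raise SegmentationEmptyError("reformatted image has no usable contrast")
        thr = threshold_otsu(vals)
        cand = (image.intensities < thr) & image.valid
        ball = _physical_ball(self.params.opening_radius_mm, image.frame.pixel_spacing)
        if ball is not None and cand.any():
            cand = ndimage.binary_opening(cand, structure=ball)
        if cand.any():
            labels, n = ndimage.label(cand, structure=_STRUCT_8)
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            if self.params.keep_largest:
                cand = labels == int(np.argmax(counts))
            else:
                keep = np.flatnonzero(counts >= self.params.min_component_pixels)
                cand = np.isin(labels, keep)
        if not cand.any():
            raise SegmentationEmptyError("classical 2D segmentation produced an empty mask")
        return Mask2D(frame=image.frame, data=cand.astype(np.uint8))


@dataclass
class PrecomputedVolumetricBackend:
    """Backend wrapping a fixed 3D mask (e.g. ground truth injection)."""

    mask: Mask3D
    kind: str = "volumetric"
    descriptor: str = "precomputed-mask-3d"

    def predict(self, volume: Volume3D) -> Mask3D:
        if tuple(volume.grid.shape) != tuple(self.mask.grid.shape):
            raise SegmentationEmptyError("precomputed mask grid does not match the volume")
        return self.mask


@dataclass
class MaskResamplePlanarBackend:
    """Planar backend that nearest-neighbor-resamples a fixed 3D mask onto
    the reformatted plane (ground-truth injection for the 2D stage)."""

    mask: Mask3D
    kind: str = "planar"
    descriptor: str = "resampled-truth-mask-2d"

    def predict(self, image: Reformatted2D) -> Mask2D:
        from .reformat import resample_plane
        as_volume = Volume3D(grid=self.mask.grid, data=self.mask.data.astype(np.float32))
        resampled = resample_plane(as_volume, image.frame, interpolation="nearest")
        labels = (resampled.intensities > 0.5) & resampled.valid
        if not labels.any():
            raise SegmentationEmptyError("truth mask does not intersect the reformatted plane")
        return Mask2D(frame=image.frame, data=labels.astype(np.uint8))


# ---------------------------------------------------------------------- #
# false-positive removal (largest connected component)
# ---------------------------------------------------------------------- #

def remove_false_positives(mask: Mask3D) -> Mask3D:
    """Keep exactly the largest 26-connected component of the mask.

    The needle segmentation object is assumed to have the largest volume
    among all dark objects; smaller components (other susceptibility or
    signal-void regions) are removed. Volume is measured in voxel count —
    within one grid this ranks identically to mm^3. An exact tie is broken
    toward the component containing the lexicographically smallest voxel
    index (deterministic) and logged.
    """
    if mask.n_voxels == 0:
        raise SegmentationEmptyError("cannot remove false positives from an empty mask")
    labels, n = ndimage.label(mask.data, structure=_STRUCT_26)
    if n == 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) > 1:
        # keep the component whose lexicographically smallest voxel index
        # (first voxel in C-order scan) is smallest
        flat = labels.ravel()
        firsts = [int(np.argmax(flat == lab)) for lab in tied]
        pick = int(tied[int(np.argmin(firsts))])
        log.warning("FP removal: %d components tied at %d voxels; keeping the one "
                    "with the smallest voxel index", len(tied), best)
    else:
        pick = int(tied[0])
    log.debug("FP removal: kept 1 of %d components (%d voxels)", n, best)
    return Mask3D(grid=mask.grid, data=(labels == pick).astype(np.uint8))


def count_components(mask_data: np.ndarray, connectivity_3d: bool = True) -> int:
    """Number of connected components (26-connectivity in 3D, 8 in 2D)."""
    struct = _STRUCT_26 if mask_data.ndim == 3 else _STRUCT_8
    _, n = ndimage.label(mask_data, structure=struct)
    return int(n)


# ---------------------------------------------------------------------- #
# principal axis
# ---------------------------------------------------------------------- #

def principal_axis(mask: Mask3D) -> tuple[np.ndarray, np.ndarray]:
    """Main axis of a 3D mask: centroid and dominant covariance eigenvector.

    Computed on voxel-center *world* coordinates so anisotropic voxels do
    not bias the direction. The sign is canonicalized so the component of
    largest magnitude is positive (tip/entry orientation is decided later).
    Coincides with 3D orthogonal-distance line fitting.
    """
    pts = mask.world_coordinates()
    if pts.shape[0] < 2:
        raise DegenerateMaskError(f"principal axis needs >= 2 voxels, got {pts.shape[0]}")
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[2] - evals[1] <= 1e-9 * max(evals[2], 1.0):
        raise AxisAmbiguousError(
            f"top two covariance eigenvalues tie ({evals[2]:.3g} vs {evals[1]:.3g})"
        )
    direction = evecs[:, 2]
    k = int(np.argmax(np.abs(direction)))
    if direction[k] < 0:
        direction = -direction
    return centroid, direction


# ---------------------------------------------------------------------- #
# data augmentation (training recipe)
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class AugmentationConfig:
    """Training-time augmentation recipe: each fold applies one random
    composition of rotation, flipping, translation and zooming to image and
    mask identically, plus additive Gaussian noise to the image only.
    The default 15-fold expansion matches the training recipe of the
    reference networks; parameter ranges are configuration choices.
    """

    fold: int = 15
    rotation_max_deg: float = 15.0
    translation_max_mm: float = 10.0
    zoom_range: tuple[float, float] = (0.9, 1.1)
    flip_axes: tuple[int, ...] = (0, 1)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.zoom_range[0] <= 0 or self.zoom_range[1] <= 0:
            raise ValueError("zoom range must be positive")


def _sample_transform(rng: np.random.Generator, cfg: AugmentationConfig, grid):
    """Random rigid+zoom transform in voxel coordinates about the grid center.

    Returns (matrix, offset) for ``ndimage.affine_transform`` (output->input
    map) plus the same map as a world-space callable for registration checks.
    """
    angles = rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg, size=3)
    cx, cy, cz = np.deg2rad(angles)

    def rot(axis, a):
        c, s = np.cos(a), np.sin(a)
        m = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        m[i, i] = c; m[i, j] = -s; m[j, i] = s; m[j, j] = c
        return m

    r_world = rot(0, cx) @ rot(1, cy) @ rot(2, cz)
    flip = np.eye(3)
    for ax in cfg.flip_axes:
        if rng.random() < 0.5:
            flip[ax, ax] = -1.0
    zoom = rng.uniform(*cfg.zoom_range)
    shift_mm = rng.uniform(-cfg.translation_max_mm, cfg.translation_max_mm, size=3)

    spacing = grid.spacing
    # forward map in voxel space: v' = S^-1 (zoom * R * F) S (v - c) + c + S^-1 t
    a_vox = (zoom * r_world @ flip) * spacing[np.newaxis, :] / spacing[:, np.newaxis]
    center = (np.array(grid.shape) - 1) / 2.0
    t_vox = shift_mm / spacing
    inv = np.linalg.inv(a_vox)
    offset = center - inv @ (center + t_vox)

    def forward_world(p):
        """World-space forward map consistent with the voxel-space resample."""
        v = grid.world_to_voxel(p)
        v2 = a_vox @ (v - center) + center + t_vox
        return grid.voxel_to_world(v2)

    return inv, offset, forward_world


def augment(image: Volume3D, mask: Mask3D, config: AugmentationConfig | None = None,
            max_retries: int = 10) -> list[tuple[Volume3D, Mask3D]]:
    """Generate ``config.fold`` augmented (image, mask) pairs.

    Spatial transforms are applied identically to both (image with linear
    interpolation, mask nearest-neighbor to preserve binarity); noise goes
    on the image only. A transform that pushes the whole mask out of the
    field is regenerated with a new sub-seed, with bounded retries.
    Deterministic for a fixed seed.
    """
    config = config or AugmentationConfig()
    if tuple(image.grid.shape) != tuple(mask.grid.shape):
        raise ValueError("image and mask must share a grid")
    streams = np.random.SeedSequence(config.seed).spawn(config.fold)
    out = []
    for ss in streams:
        for attempt, child in enumerate(ss.spawn(max_retries)):
            rng = np.random.default_rng(child)
            inv, offset, fwd = _sample_transform(rng, config, image.grid)
            new_mask = ndimage.affine_transform(
                mask.data, inv, offset=offset, order=0, mode="constant", cval=0)
            if new_mask.any():
                break
        else:
            raise ValueError("augmentation repeatedly pushed the mask out of the field")
        new_img = ndimage.affine_transform(
            np.asarray(image.data, dtype=np.float32), inv, offset=offset,
            order=1, mode="nearest")
        if config.noise_sd > 0:
            new_img = new_img + rng.normal(0, config.noise_sd, new_img.shape).astype(np.float32)
        out.append((Volume3D(grid=image.grid, data=new_img),
                    Mask3D(grid=mask.grid, data=new_mask.astype(np.uint8))))
    return out


def sample_augment_transform(config: AugmentationConfig, grid, fold_index: int = 0):
    """Expose the world-space forward map of one augmentation fold (for
    registration checks against transformed landmark coordinates)."""
    ss = np.random.SeedSequence(config.seed).spawn(config.fold)[fold_index]
    rng = np.random.default_rng(ss.spawn(1)[0])
    _, _, fwd = _sample_transform(rng, config, grid)
    return fwd


# ---------------------------------------------------------------------- #
# neural training contract
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters for neural backends (soft-Dice loss, Adam)."""

    loss: str = "dice"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 200
    fine_tune_learning_rate: float = 1e-5

    def __post_init__(self):
        if self.loss != "dice":
            raise ValueError("only soft-Dice loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        for name in ("learning_rate", "batch_size", "epochs", "fine_tune_learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def neural_runtime_available() -> bool:
    return importlib.util.find_spec("torch") is not None


def train_backend(backend_factory: Callable, dataset, train_config: TrainConfig | None = None):
    """Train a neural segmentation backend (thin contract).

    ``backend_factory(dataset, train_config)`` must return an object
    satisfying :class:`SegmentationBackend`. Raises :class:`CapabilityError`
    when no neural runtime is installed — use the classical backends in that
    case.
    """
    train_config = train_config or TrainConfig()
    dataset = list(dataset)
    if not dataset:
        raise ValueError("training dataset is empty")
    if not neural_runtime_available():
        raise CapabilityError(
            "no neural runtime (torch) is installed; use ClassicalVolumetricBackend / "
            "ClassicalPlanarBackend instead"
        )
    return backend_factory(dataset, train_config)  # pragma: no cover - needs torch
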