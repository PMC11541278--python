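"""Needle tip/axis localization (pipeline Step 3) and pipeline orchestration.

The fine 2D stage fits the needle axis to the 2D segmentation by orthogonal
distance regression (total least squares: the line through the centroid
along the dominant covariance eigenvector), intersects it with the mask to
obtain the two feature endpoints, tells tip from entry by boundary
proximity, and lifts both through the reformatting plane's affine back to
3D world coordinates.

``localize_no2d`` implements the ablated baseline that skips the 2D stage
entirely: the principal axis of the coarse 3D mask is taken as the needle
axis and its intersection with the mask surface as the endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (AxisAmbiguousError, CorridorEmptyError, DegenerateMaskError,
                     NeedlePipeError, SegmentationEmptyError, StageError)
from .imgeom import Mask2D, Mask3D, Volume3D, VolumeGrid
from .reformat import (PlaneFrame, build_oblique_axial_frame, plane_to_world,
                       resample_plane)
from .seg_backend import principal_axis, remove_false_positives

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Line2D:
    """A line in in-plane (s, t) mm coordinates."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(2))
        d = np.asarray(self.direction, dtype=float).reshape(2)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("line direction must be unit length")
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class NeedleLocalization:
    """Pipeline output: tip, entry and unit axis direction in world mm."""

    tip: np.ndarray
    entry: np.ndarray
    axis_direction: np.ndarray
    provenance: str = "full_pipeline"

    def __post_init__(self):
        tip = np.asarray(self.tip, dtype=float).reshape(3)
        entry = np.asarray(self.entry, dtype=float).reshape(3)
        if np.allclose(tip, entry):
            raise NeedlePipeError("degenerate localization: tip equals entry")
        d = np.asarray(self.axis_direction, dtype=float).reshape(3)
        expected = (tip - entry) / np.linalg.norm(tip - entry)
        if np.linalg.norm(d - expected) > 1e-6:
            raise NeedlePipeError("axis_direction must equal unit(tip - entry)")
        object.__setattr__(self, "tip", tip)
        object.__setattr__(self, "entry", entry)
        object.__setattr__(self, "axis_direction", d)

    @classmethod
    def from_endpoints(cls, tip, entry, provenance="full_pipeline") -> "NeedleLocalization":
        tip = np.asarray(tip, dtype=float)
        entry = np.asarray(entry, dtype=float)
        d = tip - entry
        return cls(tip=tip, entry=entry, axis_direction=d / np.linalg.norm(d),
                   provenance=provenance)

    def to_dict(self) -> dict:
        return {"tip_mm": self.tip.tolist(), "entry_mm": self.entry.tolist(),
                "axis_direction": self.axis_direction.tolist(),
                "provenance": self.provenance}


# ---------------------------------------------------------------------- #
# 2D axis fit (orthogonal distance regression)
# ---------------------------------------------------------------------- #

def fit_axis_odr(points: np.ndarray) -> Line2D:
    """Fit a 2D line minimizing the sum of squared orthogonal distances.

    The minimizer passes through the centroid along the dominant eigenvector
    of the 2D covariance; deterministic. Raises on identical points or an
    isotropic covariance (no preferred direction).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 2 or np.allclose(pts, pts[0]):
        raise DegenerateMaskError("ODR needs at least 2 non-identical points")
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    cov = rel.T @ rel / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] - evals[0] <= 1e-9 * max(evals[1], 1.0):
        raise AxisAmbiguousError("isotropic point set: 2D axis direction ambiguous")
    d = evecs[:, 1]
    k = int(np.argmax(np.abs(d)))
    if d[k] < 0:
        d = -d
    return Line2D(point=centroid, direction=d)


def odr_residual_sum(points: np.ndarray, line: Line2D) -> float:
    """Sum of squared orthogonal distances of points to a line."""
    rel = np.asarray(points, dtype=float) - line.point
    proj = rel @ line.direction
    return float((np.einsum("ij,ij->i", rel, rel) - proj**2).sum())


def extract_endpoints(mask2d: Mask2D, line: Line2D,
                      corridor_halfwidth_mm: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Intersect the fitted 2D axis with the segmentation mask.

    Among mask pixels within ``corridor_halfwidth_mm`` orthogonal distance
    of the line, the two extreme scalar projections are taken and projected
    onto the line, so both endpoints lie exactly on the fitted axis.
    Returned in canonical order (smaller projection first).
    """
    if mask2d.n_pixels == 0:
        raise SegmentationEmptyError("cannot extract endpoints from an empty 2D mask")
    idx = np.argwhere(mask2d.data > 0)
    pts = idx * np.asarray(mask2d.frame.pixel_spacing)
    rel = pts - line.point
    proj = rel @ line.direction
    perp2 = np.einsum("ij,ij->i", rel, rel) - proj**2
    ok = perp2 <= corridor_halfwidth_mm**2
    if not ok.any():
        raise CorridorEmptyError(
            "no mask pixels within the axis corridor: segmentation and fitted axis disagree"
        )
    p = proj[ok]
    end_a = line.point + p.min() * line.direction
    end_b = line.point + p.max() * line.direction
    return end_a, end_b


# ---------------------------------------------------------------------- #
# tip vs entry disambiguation
# ---------------------------------------------------------------------- #

def _disambiguate_3d(point_a: np.ndarray, point_b: np.ndarray, grid: VolumeGrid,
                     tip_rule="boundary") -> tuple[np.ndarray, np.ndarray, str]:
    """Return (tip, entry, rule_log) among two world points.

    Default rule: the entry point of a needle intervention lies at the skin
    near the imaged surface, so the endpoint closer to the volume's physical
    boundary is the entry and the other the tip. An exact tie is broken by
    taking the more inferior endpoint as the entry. A manual override
    ``("manual", direction)`` declares the tip to be the endpoint with the
    larger projection on ``direction``.
    """
    if isinstance(tip_rule, (tuple, list)) and tip_rule[0] == "manual":
        d = np.asarray(tip_rule[1], dtype=float)
        if (point_a - point_b) @ d > 0:
            return point_a, point_b, "manual-direction"
        return point_b, point_a, "manual-direction"
    da = grid.boundary_distance_mm(point_a)
    db = grid.boundary_distance_mm(point_b)
    if abs(da - db) <= 1e-9:
        log.warning("tip rule: endpoints equidistant from the boundary (%.3f mm); "
                    "choosing the more inferior endpoint as entry", da)
        if point_a[2] < point_b[2]:
            return point_b, point_a, "boundary-tie-inferior-entry"
        return point_a, point_b, "boundary-tie-inferior-entry"
    if da < db:  # a is nearer the surface -> entry
        return point_b, point_a, "boundary-proximity"
    return point_a, point_b, "boundary-proximity"


def disambiguate_tip(end_a: np.ndarray, end_b: np.ndarray, frame: PlaneFrame,
                     volume_grid: VolumeGrid, tip_rule="boundary"
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Decide which in-plane endpoint is the tip and which the entry.

    Both endpoints are lifted to 3D and the boundary-proximity rule applied;
    the applied rule is logged. Returns ``(tip2d, entry2d)``.
    """
    a3 = plane_to_world(np.asarray(end_a), frame)
    b3 = plane_to_world(np.asarray(end_b), frame)
    tip3, entry3, rule = _disambiguate_3d(a3, b3, volume_grid, tip_rule)
    log.debug("tip/entry disambiguation rule applied: %s", rule)
    if np.allclose(tip3, a3):
        return np.asarray(end_a, dtype=float), np.asarray(end_b, dtype=float)
    return np.asarray(end_b, dtype=float), np.asarray(end_a, dtype=float)


# ---------------------------------------------------------------------- #
# no-2D baseline
# ---------------------------------------------------------------------- #

def localize_no2d(mask3d: Mask3D, tip_rule="boundary") -> NeedleLocalization:
    """Baseline localization from the 3D mask alone (no 2D refinement).

    The principal axis of the mask is the needle axis; the extreme
    projections of mask voxel centers onto that axis (lifted to the axis
    line) are the candidate endpoints, disambiguated by the boundary rule.
    """
    centroid, direction = principal_axis(mask3d)
    pts = mask3d.world_coordinates()
    proj = (pts - centroid) @ direction
    p_lo = centroid + proj.min() * direction
    p_hi = centroid + proj.max() * direction
    tip, entry, rule = _disambiguate_3d(p_lo, p_hi, mask3d.grid, tip_rule)
    log.debug("no-2d tip/entry rule applied: %s", rule)
    return NeedleLocalization.from_endpoints(tip, entry, provenance="no_2d_baseline")


# ---------------------------------------------------------------------- #
# full pipeline
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class PipelineConfig:
    """Geometric parameters of the coarse-to-fine pipeline."""

    pixel_spacing: tuple[float, float] = (1.35, 1.35)
    margin_mm: float = 20.0
    corridor_halfwidth_mm: float = 3.0
    interpolation: str = "linear"
    tip_rule: object = "boundary"
    no_2d: bool = False
    fallback_no2d: bool = True


@dataclass
class PipelineIntermediates:
    """Audit trail of one pipeline run."""

    mask3d_raw: Mask3D = None
    mask3d: Mask3D = None
    axis_centroid: np.ndarray = None
    axis_direction: np.ndarray = None
    frame: PlaneFrame = None
    reformatted: object = None
    mask2d: Mask2D = None
    line2d: Line2D = None
    stage_log: list = field(default_factory=list)


def run_pipeline(volume: Volume3D, backend3d, backend2d=None,
                 config: PipelineConfig | None = None
                 ) -> tuple[NeedleLocalization, PipelineIntermediates]:
    """Execute the coarse-to-fine localization pipeline on one volume.

    Step 1: volumetric segmentation + largest-component false-positive
    removal. Step 2: oblique axial reformatting along the mask's main axis.
    Step 3: planar segmentation of the reformatted image, ODR axis fit,
    endpoint extraction, tip/entry disambiguation, and 2D->3D lifting.
    With ``config.no_2d`` the baseline skips Steps 2-3 and localizes from
    the 3D mask directly. Stage failures propagate as :class:`StageError`
    carrying the stage name; an empty Step-3 mask falls back to the no-2D
    baseline with a warning (unless ``fallback_no2d`` is disabled).
    """
    cfg = config or PipelineConfig()
    inter = PipelineIntermediates()

    def stage(name, fn):
        try:
            result = fn()
        except NeedlePipeError as exc:
            if isinstance(exc, SegmentationEmptyError) and name == "step1-segmentation":
                raise StageError(name, SegmentationEmptyError("needle not detected")) from exc
            raise StageError(name, exc) from exc
        inter.stage_log.append(name)
        return result

    inter.mask3d_raw = stage("step1-segmentation", lambda: backend3d.predict(volume))
    inter.mask3d = stage("step1-fp-removal", lambda: remove_false_positives(inter.mask3d_raw))

    if cfg.no_2d:
        loc = stage("no2d-localization", lambda: localize_no2d(inter.mask3d, cfg.tip_rule))
        return loc, inter

    def _step2():
        centroid, direction = principal_axis(inter.mask3d)
        inter.axis_centroid, inter.axis_direction = centroid, direction
        frame = build_oblique_axial_frame(centroid, direction, inter.mask3d,
                                          margin_mm=cfg.margin_mm,
                                          pixel_spacing=cfg.pixel_spacing)
        inter.frame = frame
        return resample_plane(volume, frame, interpolation=cfg.interpolation)

    inter.reformatted = stage("step2-reformat", _step2)

    try:
        inter.mask2d = backend2d.predict(inter.reformatted)
        inter.stage_log.append("step3-segmentation")
    except SegmentationEmptyError as exc:
        if not cfg.fallback_no2d:
            raise StageError("step3-segmentation", exc) from exc
        log.warning("2D segmentation empty (%s); falling back to the no-2D baseline", exc)
        inter.stage_log.append("step3-segmentation-empty-fallback-no2d")
        loc = stage("no2d-localization", lambda: localize_no2d(inter.mask3d, cfg.tip_rule))
        return loc, inter

    def _step3():
        idx = np.argwhere(inter.mask2d.data > 0)
        pts = idx * np.asarray(inter.frame.pixel_spacing)
        line = fit_axis_odr(pts)
        inter.line2d = line
        end_a, end_b = extract_endpoints(inter.mask2d, line, cfg.corridor_halfwidth_mm)
        tip2d, entry2d = disambiguate_tip(end_a, end_b, inter.frame, volume.grid,
                                          cfg.tip_rule)
        tip3 = plane_to_world(tip2d, inter.frame)
        entry3 = plane_to_world(entry2d, inter.frame)
        return NeedleLocalization.from_endpoints(tip3, entry3, provenance="full_pipeline")

    loc = stage("step3-localization", _step3)
    return loc, inter
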