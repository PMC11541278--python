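"""Evaluation metrics, mask perturbation models, cross-validation harness,
and the nonparametric statistical comparison procedure.

Metrics follow interventional-MRI usage: Dice overlap of the raw
segmentations (before post-processing), the 3D Euclidean tip error
``epsilon_tip`` in mm, and the acute angle ``alpha`` (degrees) between
predicted and reference needle axes. The axis angle uses the absolute-dot
convention so it is independent of the tip/entry orientation decision.

Group comparisons use the omnibus-then-pairwise recipe standard for
non-normal paired metrics: a Kruskal-Wallis gate for more than two samples,
then pairwise Wilcoxon signed-rank tests with Bonferroni correction;
exactly two samples are compared with Wilcoxon directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .errors import DegenerateMaskError, GeometryError, NeedlePipeError
from .imgeom import Mask2D, Mask3D
from .localize import NeedleLocalization
from .seg_backend import principal_axis

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class EvalRecord:
    """Per-case metric record."""

    case_id: str
    pipeline_variant: str = "full"
    dice3d: float = np.nan
    dice2d: float = np.nan
    tip_error_mm: float = np.nan
    axis_error_deg: float = np.nan

    def __post_init__(self):
        for name, lo, hi in (("dice3d", 0, 1), ("dice2d", 0, 1),
                             ("tip_error_mm", 0, np.inf), ("axis_error_deg", 0, 90)):
            v = getattr(self, name)
            if not np.isnan(v) and not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


# ---------------------------------------------------------------------- #
# metrics
# ---------------------------------------------------------------------- #

def _same_geometry(a, b) -> bool:
    if isinstance(a, Mask3D) and isinstance(b, Mask3D):
        return (tuple(a.grid.shape) == tuple(b.grid.shape)
                and np.allclose(a.grid.affine, b.grid.affine, atol=1e-6))
    if isinstance(a, Mask2D) and isinstance(b, Mask2D):
        fa, fb = a.frame, b.frame
        return (fa.size == fb.size
                and np.allclose(fa.origin, fb.origin, atol=1e-6)
                and np.allclose(fa.u_axis, fb.u_axis, atol=1e-9)
                and np.allclose(fa.v_axis, fb.v_axis, atol=1e-9))
    return False


def dice(a, b) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two masks on the same grid.

    Two empty masks agree on absence (1.0); empty vs nonempty is 0.0.
    """
    if not _same_geometry(a, b):
        raise GeometryError("dice requires masks on the same grid/frame")
    na, nb = int(a.data.sum()), int(b.data.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def tip_error(pred: NeedleLocalization, ref: NeedleLocalization) -> float:
    """Euclidean distance (mm) between predicted and reference tips."""
    return float(np.linalg.norm(pred.tip - ref.tip))


def axis_error(pred, ref) -> float:
    """Acute angle (degrees, in [0, 90]) between two needle axes.

    Accepts localizations or raw unit direction vectors; antiparallel
    directions give 0 by the absolute-dot convention.
    """
    d1 = pred.axis_direction if isinstance(pred, NeedleLocalization) else np.asarray(pred, float)
    d2 = ref.axis_direction if isinstance(ref, NeedleLocalization) else np.asarray(ref, float)
    for d in (d1, d2):
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError("axis_error requires unit direction vectors")
    return float(np.degrees(np.arccos(np.clip(abs(float(d1 @ d2)), 0.0, 1.0))))


def mm_to_pixels(error_mm: float, in_plane_spacing_mm: float) -> float:
    """Express a distance error in in-plane pixels (unrounded)."""
    if in_plane_spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    return error_mm / in_plane_spacing_mm


# ---------------------------------------------------------------------- #
# mask perturbation models
# ---------------------------------------------------------------------- #

def perturb_mask(mask: Mask3D, model: str, magnitude_mm: float = 0.0,
                 seed: int = 0) -> Mask3D:
    """Deterministic seeded mask perturbation emulating segmentation and
    intra-reader variability near the needle tip.

    Models
    ------
    ``tip_undersegment``
        Remove the ``magnitude_mm`` of the feature nearest the tip end of
        the principal axis (segmentation stopping short of the tip).
    ``tip_oversegment``
        Attach a sphere of radius ``magnitude_mm`` at the tip end
        (blooming / over-segmentation; attached, so it survives
        largest-component false-positive removal).
    ``attached_blob``
        Attach a sphere of radius ``magnitude_mm`` at a seeded random
        boundary voxel of the mask.
    ``jitter``
        Translate the whole mask by a random offset of typical size
        ``magnitude_mm`` (rounded to voxels); zero magnitude is identity.
    """
    from .localize import _disambiguate_3d  # deep end = tip, same rule as the pipeline

    if mask.n_voxels == 0:
        raise DegenerateMaskError("cannot perturb an empty mask")
    _, n = ndimage.label(mask.data, structure=_STRUCT_26)
    if n != 1:
        raise NeedlePipeError(f"perturb_mask requires a single-component mask, got {n}")
    rng = np.random.default_rng([seed, 0x9E3779])
    grid = mask.grid

    if model == "jitter":
        if magnitude_mm == 0:
            return mask
        shift_mm = rng.normal(0.0, magnitude_mm / np.sqrt(3.0), size=3)
        shift_vox = np.rint(shift_mm / grid.spacing).astype(int)
        data = np.roll(mask.data, shift_vox, axis=(0, 1, 2))
        return Mask3D(grid=grid, data=data)

    centroid, direction = principal_axis(mask)
    pts = mask.world_coordinates()
    proj = (pts - centroid) @ direction
    p_lo = centroid + proj.min() * direction
    p_hi = centroid + proj.max() * direction
    tip_end, _, _ = _disambiguate_3d(p_lo, p_hi, grid)
    sign = 1.0 if np.allclose(tip_end, p_hi) else -1.0

    if model == "tip_undersegment":
        cut = (proj.max() if sign > 0 else -proj.min()) - magnitude_mm
        keep = sign * proj <= cut
        if not keep.any():
            raise NeedlePipeError("tip_undersegment would empty the mask")
        data = np.zeros(grid.shape, dtype=np.uint8)
        idx = np.argwhere(mask.data > 0)[keep]
        data[tuple(idx.T)] = 1
        return Mask3D(grid=grid, data=data)

    if model in ("tip_oversegment", "attached_blob"):
        if model == "tip_oversegment":
            center = tip_end
        else:
            boundary = mask.data.astype(bool) & ~ndimage.binary_erosion(mask.data.astype(bool))
            bidx = np.argwhere(boundary)
            center = grid.voxel_to_world(bidx[rng.integers(len(bidx))])
        data = mask.data.copy()
        data |= _sphere_mask(grid, center, magnitude_mm)
        return Mask3D(grid=grid, data=data)

    raise ValueError(f"unknown perturbation model {model!r}")


def _sphere_mask(grid, center, radius_mm) -> np.ndarray:
    lo_w, hi_w = np.asarray(center) - radius_mm, np.asarray(center) + radius_mm
    corners = np.array([[lo_w[k] if b & (1 << k) == 0 else hi_w[k] for k in range(3)]
                        for b in range(8)])
    idx = grid.world_to_voxel(corners)
    lo = np.maximum(np.floor(idx.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(idx.max(axis=0)).astype(int), np.array(grid.shape) - 1)
    out = np.zeros(grid.shape, dtype=np.uint8)
    if np.any(lo > hi):
        return out
    ii, jj, kk = np.meshgrid(*(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij")
    pts = grid.voxel_to_world(np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
    d2 = np.einsum("ij,ij->i", pts - center, pts - center)
    out[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = \
        (d2 <= radius_mm**2).reshape(ii.shape)
    return out


# ---------------------------------------------------------------------- #
# cross-validation harness
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class FoldPlan:
    """Leave-one-group-out fold assignment."""

    groups: tuple
    folds: tuple  # of (train_group_tuple, validation_group)

    def __post_init__(self):
        val = [f[1] for f in self.folds]
        if sorted(val) != sorted(self.groups):
            raise ValueError("folds must use each group as validation exactly once")
        for train, v in self.folds:
            if set(train) | {v} != set(self.groups) or v in train:
                raise ValueError("each fold's train/validation sets must partition the groups")


def make_fold_plan(groups) -> FoldPlan:
    """Leave-one-group-out plan: one fold per group."""
    groups = tuple(groups)
    if len(set(groups)) != len(groups):
        raise ValueError("group labels must be unique")
    folds = tuple((tuple(g for g in groups if g != v), v) for v in groups)
    return FoldPlan(groups=groups, folds=folds)


def crossval_harness(cases_by_group: dict, k: int, evaluate,
                     fit=None) -> tuple[FoldPlan, list]:
    """Leave-one-group-out cross-validation.

    ``cases_by_group`` maps a group label (one experiment) to its list of
    cases. ``k`` must equal the number of groups. Per fold, ``fit`` (if
    given) receives the pooled training cases and returns backend
    parameters; ``evaluate(validation_cases, params)`` returns a list of
    :class:`EvalRecord`. Records from all folds are concatenated.
    """
    if len(cases_by_group) < 2:
        raise ValueError("cross-validation requires at least 2 groups")
    if k != len(cases_by_group):
        raise ValueError(f"k={k} must equal the number of groups ({len(cases_by_group)})")
    plan = make_fold_plan(cases_by_group.keys())
    records = []
    for train_groups, val_group in plan.folds:
        train_cases = [c for g in train_groups for c in cases_by_group[g]]
        params = fit(train_cases) if fit is not None else None
        records.extend(evaluate(list(cases_by_group[val_group]), params))
    return plan, records


def summarize(values) -> dict:
    """Median and IQR of a metric sample, reported as median [IQR]."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "iqr": (float(q1), float(q3)), "n": int(v.size)}


# ---------------------------------------------------------------------- #
# statistical comparison
# ---------------------------------------------------------------------- #

def _safe_wilcoxon(x, y) -> float:
    d = np.asarray(x, float) - np.asarray(y, float)
    if np.all(d == 0):
        return 1.0
    # exact null distribution is tractable up to n ~ 50 and matters for the
    # extreme all-positive-difference case; fall back on the normal
    # approximation for larger samples or degenerate inputs
    method = "exact" if d.size <= 50 and np.all(d != 0) else "auto"
    for m in (method, "auto"):
        try:
            return float(stats.wilcoxon(x, y, method=m).pvalue)
        except ValueError:
            continue
    return 1.0


def compare_groups(samples: dict, paired: bool = True, alpha: float = 0.05) -> dict:
    """Omnibus-then-pairwise nonparametric comparison of metric samples.

    For more than two samples a Kruskal-Wallis omnibus test gates the
    pairwise Wilcoxon signed-rank tests (skipped when not significant);
    exactly two samples are compared with Wilcoxon directly, with no
    omnibus test. Pairwise p-values are Bonferroni-corrected (multiplied by
    the number of comparisons, capped at 1).
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("compare_groups needs at least 2 samples")
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if paired:
        lengths = {len(v) for v in arrays.values()}
        if len(lengths) != 1:
            raise ValueError("paired comparison requires samples of equal length")
    report = {
        "alpha": alpha,
        "paired": paired,
        "summaries": {k: summarize(v) for k, v in arrays.items()},
        "omnibus": None,
        "pairwise": [],
    }

    if len(names) > 2:
        vals = list(arrays.values())
        if all(np.array_equal(v, vals[0]) for v in vals[1:]) or \
                len({x for v in vals for x in v.tolist()}) == 1:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*vals)
        report["omnibus"] = {"test": "kruskal-wallis", "statistic": float(h),
                             "pvalue": float(p), "significant": bool(p < alpha)}
        if p >= alpha:
            return report

    pairs = [(names[i], names[j]) for i in range(len(names))
             for j in range(i + 1, len(names))]
    m = len(pairs)
    for a, b in pairs:
        if paired:
            p_raw = _safe_wilcoxon(arrays[a], arrays[b])
            test = "wilcoxon-signed-rank"
        else:
            p_raw = float(stats.mannwhitneyu(arrays[a], arrays[b]).pvalue)
            test = "mann-whitney-u"
        p_adj = min(1.0, p_raw * m)
        report["pairwise"].append({
            "pair": (a, b), "test": test, "p_raw": p_raw,
            "p_bonferroni": p_adj, "significant": bool(p_adj < alpha),
        })
    return report
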