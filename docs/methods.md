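# Methods

This note documents the models, parameter choices and numerical decisions
behind `needlepipe`, and what the synthetic validation does and does not
establish about behavior on clinical data.

## Coordinate conventions

World coordinates are RAS+ millimeters. Voxel indices are 0-based and refer
to voxel centers; fractional indices are legal everywhere (interpolation,
sub-voxel localization). Grid orientation is stored explicitly as an
orthonormal 3×3 matrix and is never silently normalized — a non-orthonormal
orientation is an error, because a sheared basis would corrupt the
axis-angle metric. All physical-space computations (principal axis, plane
construction, distances) are done in world mm so the anisotropic voxels of
the acquisition grid (1.35 × 1.35 × 1.5 mm) cannot bias directions.

## Phantom model

A phantom is background plus needle:

- **Background** — a Gaussian random field with correlation length
  `background_texture_scale` (default 2.5 mm, a granular parenchyma-like
  speckle), renormalized to `background_texture_sd` (default 3, i.e. 3% of
  the default mean 100) around `background_mean`, plus i.i.d. Gaussian
  noise `noise_sd` (default 5). The texture scale is deliberately short:
  broad smooth fields would create large connected dark dips that no
  volume-based post-processing could distinguish from a needle void,
  which is not what needle-bearing anatomy looks like.
- **Needle feature** — a cylinder of radius `needle_radius` (default
  2.5 mm) with *flat* end caps between entry and tip, optionally plus a
  sphere of `tip_bloom_radius` centered at the tip. Voxels whose centers
  fall inside are darkened multiplicatively by `void_contrast` (default
  0.8, leaving 20% of local background). The truth mask is exactly the
  darkened voxel set; the truth tip/entry are the geometric cap centers.
  Flat caps make the feature extremity coincide with the true tip, so tip
  recovery is meaningful to sub-voxel accuracy; a nonzero bloom
  deliberately extends the artifact ~`tip_bloom_radius` beyond the tip,
  emulating susceptibility blooming, and is exercised through the
  perturbation models rather than the defaults (default bloom 0).
- **Distractors** — ellipsoidal darkened blobs emulating other signal-void
  regions. Each is placed ≥ 4 mm clear of the needle, ≥ 8 mm off the
  needle's oblique-axial plane (they model voids elsewhere in the body, and
  this keeps the planar refinement stage's input independent of them), and
  is sized to 30–80% of the needle component's voxel-count cap
  (`distractor_max_volume_fraction`, default 0.5), so largest-component
  false-positive removal provably recovers the needle.

Sampling of study conditions (`sample_spec`) draws depth uniformly in
19.4–122.6 mm and elevation in −87.64° to 2.23° (the clinically observed
ranges), places the entry 3–10 mm inside the grid face the insertion
direction points away from (a skin-like entry), and keeps the tip ≥ 20 mm
from every face. One `numpy` SeedSequence child per phantom gives
reproducible, independent streams; there is no global random state.

What the generator does **not** model: partial-volume edges (voxels are
darkened whole, so segmentation boundaries are unrealistically crisp),
orientation-dependent susceptibility artifact shape, bevel asymmetry,
motion/breathing, coil shading, and multi-needle scenes. Passing recovery
tests therefore demonstrates the *geometric* correctness of the pipeline —
reformatting, fitting, lifting, disambiguation — not segmentation
robustness on clinical images, which is the role of trained neural
backends.

## Classical backends

**3D (Step 1).** Voxels darker than an intensity percentile are candidates.
The percentile must exceed the needle's voxel fraction (else the cut lands
inside the needle population) while staying deep in the background's dark
tail; since the fraction depends on the grid, the default auto-scales to
1.5× the largest expected feature fraction (feature volume bound
2600 mm³ ≈ a 2.5 mm-radius needle at 13 cm). The cut is then refined to the
midpoint of the widest empty intensity gap below it (when that gap spans
≥ 25% of the sub-threshold range): a signal void sits far below the
background tail, and anchoring the threshold in the gap makes the mask
invariant to small quantile shifts — adding a distractor elsewhere in the
volume cannot flip borderline background voxels. Components smaller than
`min_component_voxels` (default 100 ≈ 270 mm³) are discarded. Morphological
opening with a physical-radius ball is available but off by default: the
needle feature is only ~2 voxels thick in-plane, so opening erodes it,
while the component-size floor already removes noise speckle.

**2D (Step 3).** Otsu's threshold on the valid (in-volume) pixels of the
reformatted image, keeping the largest 8-connected dark component. The
needle bar versus background is strongly bimodal on this plane, so Otsu is
robust across insertion depths. Out-of-volume padding is excluded from the
threshold computation and forced to background, so segmentation cannot
hallucinate structure from padding.

**False-positive removal** keeps exactly the largest 26-connected component
(8-connected in 2D). 26-connectivity is used because oblique, thin
structures fragment under face connectivity. "Largest" is by voxel count —
identical to mm³ ranking within one grid. An exact tie keeps the component
whose lexicographically smallest voxel index is smallest, and logs a
warning. The operation is idempotent.

**Neural contract.** `train_backend` validates the recipe (soft-Dice loss,
Adam, 15-fold augmentation of rotation/flip/translation/zoom plus additive
noise — ranges are configuration, applied identically to image and mask
with nearest-neighbor mask resampling) and delegates to a backend factory;
without an installed neural runtime it raises a capability error directing
users to the classical backends.

## Plane construction (Step 2)

"Oblique axial" is interpreted as the unique plane containing the needle
axis whose normal is closest to the superior–inferior axis:
`n = unit(z − (z·u)u)` for axis direction `u`. When the needle is parallel
to S–I (|projection| < 1e-6) the anterior–posterior axis is projected
instead, and the fallback is logged. In-plane basis: `u_axis` = needle
axis, `v_axis = n × u`; frame extent = the mask's in-plane bounding box
plus a 20 mm margin, rounded up to even pixel counts, at the native
in-plane spacing (1.35 mm). Resampling is linear for images and
nearest-neighbor for label volumes, with an explicit validity map for
out-of-volume pixels.

## Localization (Step 3)

The 2D axis is the orthogonal-distance-regression line — the line through
the centroid along the dominant eigenvector of the 2D point covariance,
which is the closed-form total-least-squares minimizer. Endpoints are the
extreme scalar projections of mask pixels lying within a corridor of
half-width 3 mm (≈ 2 pixels) around the axis, projected onto the axis:
the corridor makes the mask/axis intersection robust to ragged mask edges,
and reporting on-axis points makes ε_tip insensitive to single-pixel
roughness. An empty corridor is an error signaling axis/segmentation
disagreement.

Tip versus entry: the entry point of a percutaneous intervention lies at
the skin near the imaged surface, so the endpoint whose 3D position is
closer to the volume's physical boundary is the entry. Exact ties fall to
the more inferior endpoint (logged); a manual override
(`tip_rule=("manual", direction)`) declares the tip by projection sign.
The no-2D baseline applies the same construction directly to the 3D mask:
principal axis, extreme projections, boundary rule.

If the 2D segmentation comes back empty the pipeline degrades gracefully
to the no-2D baseline with a warning rather than aborting; every stage
decision (components removed, plane fallback, tip rule, 2D fallback) is
logged for audit.

## Statistics

`compare_groups` mirrors the field's convention for paired non-normal
metrics: Kruskal–Wallis omnibus for > 2 samples gating pairwise Wilcoxon
signed-rank tests; exactly two samples go straight to Wilcoxon. The exact
signed-rank null is used for n ≤ 50 without zero differences (the normal
approximation is wildly wrong in the extreme all-positive-difference
regime); Bonferroni correction multiplies raw p-values by the number of
pairwise comparisons, capped at 1. Degenerate inputs (all samples
identical) report p = 1 rather than erroring. Summaries are median [IQR],
recomputed directly from the per-case records.

## Validation problem sizes

The recovery studies use 50 phantoms on the full acquisition grid
(176 × 256 × 120) spanning the complete depth and angle ranges — large
enough for stable medians while keeping the suite and the acceptance
script around a minute each on one CPU. Robustness properties
(false-positive invariance, perturbation ordering) use 10–20 phantoms on a
quarter-volume preset (88 × 128 × 60 at native spacing) with depths
truncated to fit. The cross-validation harness and `demo` default to the
small preset for the same reason.

## Known limitations

- Classical backends assume the needle void is the darkest and largest
  dark structure; heavy artifacts or air-filled bowel near the needle
  would defeat them (the neural contract exists for that regime).
- Single straight needle only; no curvature model, no multi-needle scenes.
- The boundary-proximity tip rule assumes the entry is nearer a volume
  face than the tip; unusual coil/FOV placements may need the manual rule.
- Dice of two empty masks is defined as 1.0 (agreement on absence),
  empty-vs-nonempty as 0.0.
- `jitter` mask perturbation translates by whole voxels (wrap-around roll);
  it is intended for masks away from the volume edge.
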