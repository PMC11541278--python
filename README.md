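# needlepipe

Automatic 3D needle localization for intra-procedural MRI.

During MRI-guided percutaneous interventions (e.g. liver biopsy or
ablation), a metallic needle appears on T1-weighted gradient-echo images as
an elongated signal void produced by susceptibility effects. Confirming the
needle's 3D tip position and axis orientation between adjustment steps is
currently a manual, minutes-long task; `needlepipe` automates it with a
coarse-to-fine pipeline:

1. **Step 1 — coarse 3D segmentation.** A volumetric backend segments the
   needle feature in the 3D volume; a false-positive removal module keeps
   only the largest 26-connected component (the needle void is the largest
   dark object; smaller voids elsewhere in the body are discarded).
2. **Step 2 — oblique axial reformatting.** The principal axis of the 3D
   mask (dominant eigenvector of the voxel-center covariance, in world mm)
   defines the needle axis; the volume is resampled on the plane containing
   that axis whose normal is closest to the superior–inferior direction.
3. **Step 3 — fine 2D localization.** A planar backend re-segments the
   needle on the reformatted image; the 2D axis is fitted by orthogonal
   distance regression (total least squares), its intersection with the
   mask gives the tip and entry point, and both are lifted back to 3D
   through the plane's affine.

Segmentation is a pluggable contract: the repository ships deterministic
classical backends (adaptive dark-tail thresholding in 3D, Otsu in 2D) so
the whole geometric pipeline runs and is testable without trained weights;
neural backends (e.g. transformer-based encoder–decoders) can be bound to
the same contract when a neural runtime is installed. A `--no-2d` variant
skips Step 3 and reads tip/entry directly off the 3D mask, serving as the
ablation baseline.

Because no clinical volumes ship with the package, a first-class synthetic
phantom module generates MR-like volumes (acquisition geometry
176 × 256 × 120 voxels at 1.35 × 1.35 × 1.5 mm) containing a needle void
with exact ground-truth tip, entry, axis and mask, over clinically observed
insertion conditions (depth 1.94–12.26 cm, needle-to-axial-plane angle
−87.64° to 2.23°). Everything is validated by parameter recovery against
this generator.

## Metrics

For predicted and reference localizations, the package reports

- **ε_tip** — Euclidean distance (mm) between predicted and reference tips;
- **α** — acute angle (degrees) between predicted and reference axes,
  `arccos |d_pred · d_ref|`, independent of tip/entry orientation;
- **Dice** — `2|A∩B| / (|A|+|B|)` overlap of raw segmentations.

Group comparisons follow the nonparametric recipe standard for paired,
non-normal metrics: Kruskal–Wallis omnibus gate for more than two samples,
then pairwise Wilcoxon signed-rank tests with Bonferroni correction.

## Worked example

```bash
needlepipe demo --seed 7 --n 10 --out-dir demo/
```

simulates ten quarter-volume phantoms, runs both pipeline variants, and
prints:

```
variant  tip err mm (median [IQR])      axis err deg (median [IQR])
full     0.50 [0.39, 0.76]             0.33 [0.14, 0.68]
no_2d    0.20 [0.15, 0.49]             0.14 [0.11, 0.32]
```

Both variants recover the needle to well under a voxel on clean coarse
masks; the full pipeline's advantage appears when the coarse mask is
corrupted near the tip (over-/under-segmentation), where the 2D refinement
re-reads the image while the no-2D baseline inherits the corrupted extent —
see `tests/test_acceptance.py`.

Other entry points:

```bash
needlepipe simulate --out-dir data/ --n 5 --seed 3          # phantoms + truth JSON
needlepipe localize --volume data/phantom000.nii.gz \
                    --out loc.json [--no-2d]                # one volume -> tip/axis
needlepipe evaluate --pred-dir data/ --truth-dir data/ --out report/
needlepipe crossval --groups 7 --cases-per-group 7 --out cv/  # leave-one-group-out
```

`localize` writes `{tip_mm, entry_mm, axis_direction, provenance,
stage_log}`; every run embeds a config hash and per-stage log (components
removed, plane fallback, tip rule, 2D fallback) for auditability.

## Layout

- `needlepipe.imgeom` — grids, volumes, masks, voxel↔world transforms, NIfTI I/O
- `needlepipe.phantom` — synthetic phantom generator and condition sampling
- `needlepipe.seg_backend` — backend contract, classical backends, FP removal,
  principal axis, augmentation recipe, training contract
- `needlepipe.reformat` — oblique axial plane construction and resampling
- `needlepipe.localize` — ODR fit, endpoint extraction, tip/entry rule,
  no-2D baseline, pipeline orchestration
- `needlepipe.evaluation` — metrics, mask perturbation models,
  cross-validation harness, statistics
- `needlepipe.cli` — `needlepipe` command-line entry points

See `docs/methods.md` for the model, parameter choices, and limitations.
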