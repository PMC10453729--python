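# Methods

## Model

Evaluation reduces a ground-truth/prediction mask pair to the binary
confusion counts TP, FP, TN, FN over the pixel (or voxel) grid; every
metric is a pure function of those four integers. Actual positives are
P = TP + FN, actual negatives N = TN + FP; a *weak label* is a ground
truth with P = 0, which forces TP = FN = 0. Volumes are counted flat —
no anisotropy or spacing weighting — because every metric here is
orientation- and geometry-invariant by construction.

The composite metric MISm is piecewise: the Dice similarity coefficient
2TP/(2TP+FP+FN) when P > 0, and the weighted specificity
α·TN/((1−α)·FP+α·TN) when P = 0. Its totality follows from two facts:
when P > 0 the DSC denominator is at least 2P > 0, and when P = 0 on a
nonempty image fp + tn = N equals the full grid, so the wSpec
denominator is positive for any α ∈ (0,1). The P > 0 branch reuses the
DSC arithmetic path verbatim, so the two are bitwise equal there, and
the test suite asserts that.

Undefined values are a first-class result state (`MetricResult.value is
None`, serialized as the string `undefined`), never an exception and
never imputed as 0. DSC is undefined exactly when TP = FP = FN = 0 and
specificity exactly when TN = FP = 0; the suite verifies both gap sets
by exhaustive enumeration of all cell vectors with entries in 0..6.
Zero-element images are rejected at mask construction, since every
metric on them is 0/0.

## Parameters

- **α (weighting coefficient)**, default 0.1, dimensionless. It trades
  the weight of TN against FP in the weak-label branch; at α = 0.5
  wSpec reduces algebraically to plain specificity, and smaller α
  penalizes false positives harder. Only the open interval (0,1) is
  accepted: α = 0 makes wSpec 0/0 whenever FP = 0, α = 1 pins it at 1
  whenever TN > 0 — both endpoints destroy the scoring gradient the
  metric exists to provide.
- **MCC convention**: when any confusion marginal is zero the MCC
  denominator vanishes; MCC is then taken as 0, so nMCC = (MCC+1)/2
  reads 0.5 — the same value as a prediction uncorrelated with the
  truth. This pins the interpretation anchors nMCC = 1 (perfect),
  0 (exactly inverted annotation), 0.5 (uninformative), and means every
  erroneous weak-label prediction scores 0.5 regardless of its FP load,
  which is precisely the insensitivity MISm addresses.
- **Accuracy** uses the standard (TP+TN)/total; it is always defined on
  a nonempty image but is dominated by TN under class imbalance.

## Scoring-gradient sweep

The sweep fixes the grid size N with P = 0 and varies the
false-positive load: at ratio r, fp = ⌊r·N + 0.5⌋ (half-up, so counts
stay integral) and tn = N − fp; the realized ratio fp/N is reported
next to the requested one. Defaults are N = 60000 (a 200×300 image's
worth, the scale of the worked example), 101 evenly spaced ratios, and
α ∈ {0.05, 0.1, 0.25, 0.5, 0.75} to expose the fan of curves around the
0.1 default. The independent oracle for the MISm columns is the closed
form α(1−r)/((1−α)r + α(1−r)), obtained by dividing wSpec through by N;
tests check every grid point against it rather than against any
figure-read values. On this grid accuracy is exactly 1 − r, DSC is 0
for all r > 0 (undefined at r = 0), and nMCC is constant 0.5.

## Synthetic masks

Ground truths are filled disks (balls in 3-D) rasterized by the
center-in-circle rule — a pixel is foreground iff its center lies
within Euclidean distance `radius` of the lesion center — or
all-background masks for weak-label scenarios. The brute-force
pixel-count oracle in the tests is fixed against this rule (radius 10
in 64×64 gives 317 foreground pixels). Predictions are derived by
perturbation operators: morphological dilation/erosion
(scipy.ndimage), translation along the first axis with border clipping
(no wrap-around, which would place false positives meaninglessly),
spurious disk-shaped blobs at seeded random background locations,
inversion, and the two degenerate predictions (all-empty,
all-foreground). The inversion operator exists because it is the only
way to realize the exact-complement case whose nMCC anchor is 0; the
all-foreground prediction on a lesion image does not reach it (its
TN = FN = 0 marginals trigger the MCC := 0 convention instead).

The default suite covers perfect, under-/over-segmentation, shifted,
inverted, missed-lesion, and four weak-label scenarios (perfect
empty, small FP blob, large FP blob, all-FP), deterministic given the
seed. What the generator does *not* emulate: real anatomy, intensity
texture, rater variability, multi-lesion or non-convex shapes, or
anisotropic voxels. Passing tests therefore demonstrate the metrics'
arithmetic and edge-case behavior, not performance claims about any
imaging modality.

A note on one reconstruction: a spurious blob with integer radius
cannot realize exactly fp = 5000 on a 200×300 grid (radius 39 gives
4777 pixels, radius 40 gives 5025), so the geometric version of the
worked example asserts exact agreement with the closed form at the
realized counts and agreement with 0.55 to within 0.01.

## Numerical choices

Counts are exact integers; metric arithmetic is double-precision
division, so values are exact to machine precision and comparisons
against 4-decimal printed values use |Δ| ≤ 5·10⁻⁵. Report and sweep
values are serialized with 6 decimals, undefined values as the literal
`undefined`. Dataset aggregation is macro by default — the mean of
per-image values over images where the metric is defined, with the
undefined count reported separately — because pooling counts (micro,
available via a flag) lets a few large-lesion images swamp weak-label
failures, and imputing undefined values as 0 would recreate the exact
DSC artifact the composite metric removes. Pair matching in the CLI is
by exact filename stem (extension-insensitive), never fuzzy.

## Limitations

MISm inherits DSC's known weaknesses on P > 0 images (insensitivity to
boundary placement, small-structure instability); it changes only the
weak-label regime. α is a free parameter: scores computed at different
α are not comparable, which is why a single community default (0.1) is
kept and the endpoints are rejected outright. Only binary (one-vs-rest)
masks are supported; soft/probabilistic predictions, multi-rater
fusion, and distance-based metrics (e.g. Hausdorff) are out of scope.
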