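# Methods

`emaclass` implements an automatic classifier for IgA-class endomysial
antibody (EmA) immunofluorescence tests. One serum sample corresponds to one
microscopy image of a stained umbilical-cord section, assigned by an expert
to one of four classes: **I** positive, **II** negative, **III** IgA
deficient, **IV** equivocal. The pipeline has four stages: image reduction
and edge enhancement, texture description, supervised classification, and
evaluation. A seeded synthetic image generator stands in for clinical data,
which is private.

## Image reduction and enhancement

Fluorescence is acquired in the green channel only, so RGB sources are
reduced to the green plane and rescaled to `[0, 1]` by the dtype maximum
(`image_io.load_image`). Edge enhancement is unsharp masking,

    out = clip(img + amount * (img - G_sigma * img), 0, 1)

with defaults `blur_sigma = 1.0` px and `amount = 1.0`. Unsharp masking was
chosen because it is the standard edge-contrast enhancer and, with a
symmetric Gaussian and reflect padding, commutes with quarter-turn rotations
— a requirement for the descriptor's invariance guarantee downstream.
Reflect padding also makes constant images exact fixed points.

## Texture descriptor

Each pixel is coded by a 4-neighbor ("+"-configuration) local binary
pattern at radius `r`: bit *i* is set when `I(neighbor_i) - I(center) >= 0`,
neighbors ordered East, North, West, South. Ties set the bit, so constant
regions code stably to 15 rather than to noise. For each of four
displacement directions (0°, 45°, 90°, 135°) at interval `d = 2r`, ordered
pairs of codes at the two endpoints are histogrammed into 4x16x16 = 1024
cells; this co-occurrence of adjacent patterns captures inter-pattern
spatial correlation that single-LBP histograms miss, while remaining
invariant to monotone intensity changes (illumination).

**Rotation invariance.** A quarter turn cyclically shifts every code and
advances each direction label by 90°; directions reaching [180°, 360°) fold
onto the opposite ray with the code pair reversed. Pooling the 1024 cells
over the orbits of this order-4 action yields **272** invariant bins
(enumeration; cross-checked by Burnside's count `(1024 + 0 + 64 + 0)/4`).
One subtlety is load-bearing: with direction labels measured in (dx, dy)
image coordinates (y down), the turn that advances labels by +90° carries
the East neighbor onto South, so the code shift inside the orbit step is
the *inverse* of the E→N→W→S shift. Using the matching shift is what makes
the pooled bins bit-identical between an image and its `np.rot90` rotations;
the mismatched convention demonstrably breaks equality. Note the action
never mixes axis-aligned (0°/90°) with diagonal (45°/135°) directions —
they are physically different pair distances (`d` vs `d*sqrt(2)`) — so a
constant image populates exactly two invariant bins.

**Valid region and pair rule.** Three scales `(r, d) in {(1,2), (2,4),
(4,8)}` share one margin-12 valid region so all scales scan the same
centers. Within `extract_features` a pair is counted only when *both*
endpoints lie inside that region; this symmetric rule is provably necessary
for exact quarter-turn equality (with a center-only rule, pairs whose far
endpoint leaves the region break the bijection for the 90°/135° directions
near the boundary). The standalone `coalbp_histogram` defaults to the
classical center rule, whose total count is exactly `4 x |valid centers|`.
The symmetric rule requires `side > 2*12 + 8`, i.e. images of at least
33 px per side. Each scale's 272-bin histogram is L1-normalized (a
probability distribution per scale) and the three blocks concatenated,
giving 816 features. Under arbitrary-angle (interpolated) rotation the
descriptor is only approximately stable; the property test uses a 384 px
noise-free textured field because at small sizes the L1 distance between
histograms is dominated by multinomial sampling error (272 bins need tens
of thousands of valid centers), and interpolation genuinely attenuates
i.i.d. pixel noise, which is a texture change rather than a rotation
artifact.

## Classification

Two methods sit behind one interface (`TrainConfig.method`), reflecting a
genuine ambiguity about whether the boosted learner or the SVM ensemble is
primary; the SVM route is the default.

* **`svm_ecoc`** — one-vs-all coding: one binary RBF-SVM per class. Per
  scorer, `(C, gamma)` is chosen from the grid `C in {0.1, 1, 10, 100}`,
  `gamma in {10^k / 816, k = -2..2}` by an inner 10-fold stratified CV on
  the training rows maximizing mean balanced accuracy (balanced, because
  one-vs-all problems are heavily imbalanced by construction). Features are
  standardized with train-only statistics stored in the model. When a class
  has too few members to cross-validate, the scorer falls back to the grid
  midpoint with `gamma = 1/p`.
* **`adaboost_trees`** — multi-class AdaBoost (SAMME exponential-loss
  updates, stage weight `ln((1-err)/err) + ln(K-1)`) over decision trees of
  `max_depth = 3` (a conventional weak-learner depth; stumps underfit
  816-dimensional histograms), 100 cycles by default. Surrogate splits for
  missing data are omitted: descriptor features are never missing.

Prediction is the argmax of the four one-vs-all scores with ties broken
toward the earlier class in (I, II, III, IV); scores are retained for ROC
construction.

**Evaluation protocol.** Ten independent stratified 70/30 Monte-Carlo
splits (per class, `round_half_up(0.7 * count)` rows to train), fully
seed-determined. The two protocol conventions described for this method — repeated 70/30 splitting and
10-fold cross-validation — are honored in distinct roles: the former as the
outer protocol, the latter as the inner hyperparameter search. Held-out
predictions are pooled across repeats into a single confusion matrix;
per-repeat accuracies (mean ± SD) and mean per-image inference time are
also reported, the latter informational only.

**Under-sampled (rebalanced) variant.** Negative-class (II) rows are removed
by seeded sampling without replacement until the negative count equals the
positive count; classes I, III, IV are untouched and survivor order is
preserved. Only the negative class is rebalanced — the rule follows the
stated removal procedure literally.

## Metrics

Accuracy is `trace/total`, error its complement (identical denominator, so
they sum to 1 exactly). Sensitivity, specificity, precision and F1 are
computed on the one-vs-rest reduction of a designated positive class
(default I) and also per class plus macro-averaged, since a single reported
scalar for a 4-class task is ambiguous about its reduction. Cohen's kappa
uses the marginal-product chance term. Any ratio with a zero denominator is
reported as `None` and flagged, never as 0. AUC is the rank (Mann-Whitney)
statistic with ties at 1/2, per class one-vs-all. An optional flag excludes
samples *predicted* equivocal from the accuracy denominator (one reading of
"inconclusive results are not counted"); it is off by default and recorded
in the report when on.

## Synthetic data generator

The generator renders stylized class-conditional textures: positives get
Poisson-distributed elliptical ring outlines (vessel walls), short oriented
line segments (reticulin fibers) and low-pass correlated mottle (Wharton's
jelly); negatives a dim background with punctate speckle; IgA-deficient
fields are near dark and noise-dominated; equivocals are positive
morphology at strongly reduced brightness and contrast. Additive Gaussian
noise is applied last and the result clipped to `[0, 1]`; everything is
seed-determined.

Two generator choices deserve justification. First, the descriptor is
invariant to intensity scaling, so class II and III cannot be told apart by
amplitude alone; the negative class therefore carries spatially structured
speckle (a real feature of nonspecific binding) and the deficient class is
i.i.d.-noise dominated with no mottle, as befits a field with no stained
tissue. Second, the equivocal class reduces the signal-to-noise ratio of
the class-I morphology rather than mixing classes, matching its clinical
meaning of weak/uncertain staining. Default per-class parameters are in
`simulate.DEFAULT_CLASS_PARAMS`; mean intensities order I > IV > II > III.
A `separability` dial interpolates all parameters toward their across-class
mean: at 0 the classes are distributionally identical and held-out accuracy
sits at chance (0.25 balanced).

What the generator does **not** emulate: optics/PSF, JPEG artifacts,
illumination gradients, dilution series, biological morphology beyond
texture statistics. Passing tests therefore demonstrate that the pipeline
recovers texture-separable classes under the stated protocol — not clinical
performance on real EmA slides.

## Problem sizes and numerical choices

The recovery experiments use 100 images per class at 96 px (evaluation) and
a 400-image imbalanced profile at 64 px (under-sampling variant) — sizes at
which the texture statistics are stable while a full 10-repeat SVM grid
search completes quickly on one core. Chance-level checks compare pooled
accuracy to 0.25 within three standard errors computed from the number of
*distinct* images, not pooled predictions, because repeats reuse samples
and are positively correlated. Stratified-split rounding is half-up per
class with the remainder to test; each split keeps at least one sample of
every present class on both sides. Degenerate inputs (single-class training
sets, empty valid regions, zero-count ratio denominators) raise or flag
rather than returning silent zeros.

## Known limitations

* The clinical headline numbers (sensitivity 82.84%, specificity 99.40%,
  accuracy 96.80% on 2597 images) were measured on private data and are not
  reproducible here; moreover those reported scalars are not mutually
  consistent with the reported confusion matrix under standard definitions
  (its trace/total is ≈ 94.07%), so metric implementations are validated on
  hand-checkable matrices instead.
* Only the 4-neighbor LBP family at integer radii is implemented; no
  uniform-pattern or 8-neighbor variants, no learned features.
* One-vs-all coding only; no exhaustive ECOC codes, cost-sensitive
  weighting, SMOTE, or probability calibration.
* AUC confidence intervals (DeLong) and multi-reader agreement are out of
  scope.
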