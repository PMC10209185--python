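# Methods

## Problem and pipeline

Colorectal biopsy slides are screened in two stages.  A convolutional
network first segments H&E tissue into 14 classes at a working resolution
of 1 μm/px (10× magnification); a shallow classifier then turns the
segmentation of each tissue fragment into one of four ordinal risk grades
(other < hyperplasia < low-grade dysplasia < high-risk) and labels the
slide with its worst fragment.  The two stages are deliberately decoupled:
the segmentation map stays fully inspectable, and the slide classifier
uses only interpretable summary features of it.

## Segmentation network

The model is an encoder–decoder U-Net with three deviations from the
classic design:

- the first level has 32 filters, doubling after every 2×2 max-pooling
  (`ModelSpec.base_filters`, `depth` — default 4 levels, bottleneck at
  512 filters);
- every block (two 3×3 conv + batch-norm + ReLU stages) ends by
  concatenating its input with its last feature map, a residual-style
  intra-block skip that improves gradient flow;
- the decoder upsamples by nearest neighbor followed by a 2×2 convolution
  instead of transposed convolutions, avoiding checkerboard artifacts.

Convolutions are same-padded so the output grid aligns with the input
tile; the original U-Net's valid-padding crop is not used because aligned
outputs make tile stitching trivial.  Weights follow He fan-in
initialization; inputs are RGB scaled to [0, 1]; the head is a 1×1
convolution to C classes with per-pixel softmax.  The per-block layer
count and normalization are choices of this implementation (they are
config-visible), as is the exact depth.

The network core (`coloseg.nn`) is a compact channels-last numpy
implementation with hand-written backward passes and Adam; single
precision is used throughout the network (the loss layer runs in double
precision).  Construction is seed-deterministic to the bit.

## Loss functions

Four objectives are interchangeable through `LossConfig`; all operate on
flat pixel batches, ignore-labeled pixels contribute exactly zero, and all
return analytic gradients (validated against central differences to
relative error ≤ 1e−3).

- **Cross-entropy / focal** act on softmax probabilities.  Focal defaults
  α=0.25, γ=2 follow the recommendation of the loss's original authors.
  Probabilities are clamped at 1e−12 before logarithms: both losses are
  unbounded at ŷ→0 and training must not NaN.
- **Bi-tempered** acts on raw activations.  The tempered-softmax
  normalizer λ is found by bisection on the monotone residual
  Σ exp_{t₂}(â − λ) − 1 inside the analytic bracket
  [max â, max â − log_{t₂}(1/C)], tolerance 1e−9, cap 100 iterations;
  bisection is unconditionally convergent and the residual after
  convergence is ≤ 1e−8 in all tested regimes (t₂ up to 4).  Defaults
  t₁=0.8, t₂=1.2 follow the reference implementation.  The one-hot zero
  entries of the target use the conventional limits (0·log_t 0 = 0), so
  only the −ŷ^{2−t₁}/(2−t₁) term survives for non-target classes.
- **Lovász-softmax** averages the Lovász extension of the per-class
  Jaccard loss over all |C| classes, as the definition reads; a
  present-classes-only variant is available behind
  `LossConfig.lovasz_present_only`.  Sorting ties are broken by stable
  sort on pixel index for determinism; the backward pass treats the
  permutation as locally constant, as in the reference algorithm.
- Per-pixel losses are averaged (not summed) over valid pixels so the
  learning-rate scale is batch-size invariant.

Dice loss is deliberately not offered as a training objective; the Dice
coefficient is used for evaluation only.

## Training protocol

Defaults (`TrainConfig`): 512×512 px patches at 1 μm/px, batch 5, Adam at
1e−4 with standard β parameters, at most 500 epochs of 300 steps.  The
learning rate halves whenever the monitored validation quantity has not
improved for 20 consecutive epochs (patience resets after a reduction —
the alternative, non-resetting reading would halve every epoch past the
20th); training stops after 50 non-improving epochs and the
best-validation weights are restored.  Both the schedule and the stop
monitor the validation loss by default (a Dice monitor is selectable);
using one monitor avoids the two rules disagreeing.  The optimizer choice
is Adam with its common β defaults: a momentum-style SGD would conflict
with the adaptive schedule, and Adam's defaults are the widely used
setting.

Patch sampling is class-balanced by anchoring: the anchor class of each
patch is drawn uniformly from the classes present in the training set,
then a uniform pixel of that class centers the patch.  This is the
simplest scheme that equalizes rare-class exposure and is replaceable.

Augmentation: random flips, 90° rotations (free-angle rotation exists but
is off by default to avoid mask-edge artifacts), elastic deformation,
Gaussian blur, gamma, stain, color and contrast jitter.  Geometric
transforms move image and mask together (mask nearest-neighbor);
photometric transforms never touch the mask.  Stain jitter is a
per-channel scale/shift in optical-density space — a parametric stand-in
for H&E stain variation.

## Inference

Whole images are covered by a grid of 512-px write windows; each window is
read with a 64-px context margin (reflect-padded at borders) and only the
write region of its prediction is kept, so same-padding seam effects —
which decay within the receptive-field half-width — never reach the
stitched map.  Argmax ties resolve to the lowest class index.  Images at
other pixel sizes are resampled to 1 μm/px first (area-weighted
anti-aliased downscale; upscaling is allowed but logged).  Persisted
likelihood maps are quantized to 8 bits per channel after the argmax is
taken.

## Slide classification

Fragments are 4-connected components of non-background pixels; components
under 10⁴ μm² are discarded as debris (both thresholds config-exposed;
4-connectivity is the conservative choice that never merges diagonal
touches).  Features per fragment: the normalized 14-bin histogram of all
segmented pixels, plus count, mean, min and max area (μm²) of tumor
clusters at least 30 μm².  The 30 μm² filter applies to the cluster
features only — the histogram and the stored map keep the raw
segmentation, so the map remains auditable; a hard-removal mode that
relabels sub-threshold clusters into their surrounding majority class is
provided.  Cluster areas are in μm² (pixel count × spacing²), consistent
with the threshold's unit.

The forest (1000 trees) is trained on fragments bearing their slide's
label — a weak-label choice: fragment-level truth does not exist, and
worst-grade aggregation at prediction time mirrors how pathologists grade
a slide by its most advanced lesion.  Cross-validation is stratified
5-fold by slide (no slide's fragments straddle folds); feature
standardization is learned on the training folds of each split only.
Slide probabilities are those of the worst fragment, since only the label
rule is defined by the aggregation principle.

## Evaluation

Per-class Dice 2|P∩R|/(|P|+|R|) with ignore pixels excluded; classes
absent from both maps are marked absent and excluded from the mean by
default (a zero-fill mode reproduces the plotting convention that scores
an absent class as zero — zero-filling penalizes centers that simply lack
a tissue type, hence it is not the default).  Benchmark comparison merges
the 14 classes to gland/non-gland (binary benchmarks) or
benign/malignant/other epithelium (three-way benchmarks) and optionally
relabels the reference's white lumen — pixels with mean RGB strictly
above 240 — as background, because this schema segments lumina separately
from gland tissue.  The benchmark F1 is the unweighted mean of the merged
foreground-class F1s with background excluded; whether a single benchmark
number should pool pixels instead is ambiguous, and the unweighted mean is
the documented choice.  Paired model comparison uses the two-sided
Wilcoxon signed-rank test (exact null for ≤ 25 informative pairs, normal
approximation with tie correction above; all-equal pairs return p=1).
Slide-level: one-vs-all ROC/AUC per risk class (mean ± sd across folds
when fold ids are given) and quadratic weighted kappa
κ = 1 − Σw·O / Σw·E with w_ij=(i−j)²/(K−1)², which penalizes confusions
between distant ordinal grades quadratically.

## Synthetic data

The generator emulates the *structure* of the problem, not H&E optics:
each class has a distinct base color (minimum pairwise distance enforced)
and one of four texture kinds (blob, fiber, speckle, gland-ring); gland
classes are drawn as rings around a near-white lumen (every channel
≥ 243) so the lumen rule is exercisable; label geometry comes from
argmaxed smooth random fields with coverage guarantees.  Slide cohorts
follow the diagnostic semantics: high-risk slides carry at least one tumor
cluster ≥ 100 μm², low-grade slides carry the low-grade class plus only
sub-30 μm² tumor specks (so the filter must fire for them to be clean),
hyperplasia — which has no segmentation class of its own — is expressed
purely as an elevated normal-gland + lamina-propria histogram whose gland
range overlaps the low-grade slides' gland content, and "other" slides
carry neither dysplasia nor tumor.  The default cohort composition is
292/693/36/33 (high-risk/low-grade/hyperplasia/other); the balanced
40-per-class design is used for validation runs.

Because the classes are separable by color and composition *by
construction*, passing tests demonstrate that the pipeline's mechanics —
gradients, sampling, stitching, features, cross-validation — are correct,
not that the models would reach any particular accuracy on real stained
tissue, with its stain variation, scanner differences and annotation
noise.

## Desk-scale study sizes

The validation runs use reduced sizes chosen once: the texture task is
five classes (normal glands, tumor, lamina propria, lymphocytes,
background) on 64-px tiles with a depth-2, 8-filter network trained for
20 epochs × 30 iterations at 1e−3 (the higher rate suits the much smaller
network; the full-size protocol keeps 1e−4), and the synthetic cohort is
160 slides with 160-px fragments.  The full-size defaults (512-px tiles,
depth-4/32-filter model, 500×300 protocol) remain the library defaults
throughout.

## Known limitations

- The numpy network core is single-threaded BLAS-bound; it trains the
  desk-scale models in minutes but is not meant for full-scale WSI
  training runs.
- No stain normalization at inference; stain jitter during training is a
  parametric approximation.
- The slide classifier sees only segmentation-derived features; tissue
  types outside the 14-class schema (notably hyperplasia) are recognized
  only through their histogram signature.
- Vendor-specific WSI container formats are out of scope; inputs are
  plain or pyramidal TIFF/PNG with known pixel spacing.
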