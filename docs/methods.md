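# Methods

## Problem setting

The package targets binary discrimination in small, imbalanced image
cohorts where the positive ("abnormal") class is both rare and
heterogeneous — the regime of rare-disease imaging. Direct two-class
softmax training overfits: the scarce abnormal class cannot anchor a
stable decision boundary. The implemented method instead learns a
feature space in which the *normal* class is dense and compact, then
treats abnormality as a density anomaly.

## Model

### Pseudo-color fusion

Each case consists of two registered grayscale images of the same
lesion under different contrasts (T1- and T2-roles). They are fused
into one RGB input with B = first contrast, G = second contrast, R ≡ 0,
then resized (bilinear, anti-aliased on downscale) to the network input
size, 100 × 100 by default. The red channel is structurally empty for
every cohort image, and auxiliary texture images are fed through the
same layout (texture in B and G, R ≡ 0) so that no class is trivially
identifiable by channel occupancy.

### L2-constrained softmax loss

The classifier minimizes softmax cross-entropy subject to
‖f(x)‖₂ = α, implemented as an explicit rescaling layer
x → αx/‖x‖ between the penultimate dense layer and the final C-way
classifier. With features pinned to a hypersphere, the loss can only
reduce by rotating descriptors — same-class pairs gain cosine
similarity, different-class pairs lose it — which is markedly more
stable than magnitude-based separation when one class has few
examples. Defaults: α = 80, C = 3 (normal, abnormal, texture). Soft
labels (from mixup) enter as the weighted cross-entropy; the soft form
reduces exactly to the hard form for one-hot labels. The zero vector
has no direction: the constraint layer raises a degenerate-input error,
with an optional ε-guard on the denominator (`norm_eps`) for training
stability.

### Auxiliary texture class

A third, non-medical texture class regularizes the feature extractor:
forcing the network to also separate generic visual textures keeps
early filters general and reduces overfitting to the small cohort. One
texture image per library entry (default 61) joins every training
epoch with hard label 2. Texture descriptors are *not* placed in the
LOF reference set by default (`include_textures` flag available).

### Training

Adam (lr 1 × 10⁻⁵ by default — a fine-tuning rate appropriate for a
pretrained backbone), batch size 1, up to 500 epochs with early
stopping on validation loss. The stopping rule tracks the best
validation loss and stops after `early_stop_patience` (default 20)
consecutive non-improving epochs, restoring the best weights; the
patience default is a design choice, since literal stop-at-first-
non-improvement is noise-dominated at batch size 1. Training is
deterministic for a fixed seed on fixed hardware.

Two backbones are built by the same constructor:

* `tiny_cnn` (default): three conv blocks (16/32/64 channels, stride-2
  stem, max pooling, global average pooling) into a 64-d penultimate
  dense layer — ≈29k parameters, seconds per epoch on one CPU core.
  Default frozen-layer count 0 (it is trained from scratch).
* `vgg16_transfer`: the standard 13-conv + 2-fc VGG16 topology with the
  first 10 weight-bearing layers frozen. "10 layers" is interpreted as
  weight-bearing layers counted from the input, since pooling layers
  have no parameters to freeze. Pretrained weights are loaded from a
  local `.npz` when supplied; otherwise the architecture is randomly
  initialized (structure, freezing and the norm constraint are
  independent of the initialization).

The network engine (convolution via im2col, max pooling, dense layers,
the constraint layer, reverse-mode gradients, Adam) is part of the
package and is verified against central finite differences in the test
suite; the exact Jacobian of the constraint layer is
(α/‖x‖)(I − x̂x̂ᵀ).

### Augmentation

Per epoch, each training item passes flip (p = 0.5 each axis) →
rotation (uniform in ±180°, bilinear, zero-filled corners — cohort
images are lesion crops on empty background) → random erasing
(p = 0.5, area 2–33%, aspect 0.3–3.3, uniform-noise fill, the cited
recipe's conventions) → mixup (λ ~ Beta(0.2, 0.2), pixels and labels
mixed identically). Mixup pairs are drawn across the whole epoch
stream, textures included, since all three classes train jointly;
`mixup_scope="cohort_only"` confines mixing within cohort/texture
groups. Erasing and mixup parameter values are the cited techniques'
common defaults; the source protocol does not specify them.

### Local Outlier Factor

Scoring uses the feature descriptors of the *normal training cases* as
the reference set (novelty-detection reading; `fit_scope="all_cohort"`
available). Brute-force neighbor search, squared-Euclidean distance,
k = 5. Two density definitions are implemented:

* `paper`: lrd(p) = 1 / mean_{q∈N_k(p)} d(p, q) — the raw-distance
  formula;
* `reachability`: the canonical definition with
  reach-dist_k(p, q) = max(k-distance(q), d(p, q)).

The `reachability` variant is the experiment default (it is what the
standard library implementations compute); the `paper` variant is the
formula of record for the hand-checked oracle values. Conventions:
N_k(p) includes all points at the k-distance (ties can make
|N_k| > k); lrd(q) of a reference always excludes q itself from its own
neighborhood; a query identical to a reference is scored in-sample
(leave-one-out), which keeps training-set scores finite; a query whose
neighbors all coincide with it has infinite density and is defined to
score 1.0 — a duplicate of a dense point is not an outlier. The
reachability variant is cross-checked against scikit-learn's
`LocalOutlierFactor` in the tests; the in-package implementation is the
one the pipeline runs.

### Evaluation

ROC-AUC (Mann–Whitney statistic), PR-AUC as average precision — the
step-wise rule, chosen over trapezoidal PR interpolation because linear
interpolation in PR space is optimistic — and the Youden operating
point J = sens + spec − 1, maximized over midpoints of adjacent
distinct scores with ±∞ sentinels, decision rule score > threshold,
ties on J resolved toward higher sensitivity (the screening
preference). Confidence intervals: DeLong structural-components
variance with a normal approximation for ROC-AUC; a class-stratified
case-resampling bootstrap (default 2000 replicates, percentile 2.5/97.5)
for PR-AUC, sensitivity and specificity. Sensitivity/specificity are
bootstrapped at the *fixed* full-sample Youden threshold, isolating
sampling noise in the error rates from threshold re-estimation.
Following the reference protocol, the operating threshold is derived on
the test ROC itself; every report carries
`threshold_source: "test_youden"` to make that optimism explicit, and a
validation-derived threshold can be substituted by the caller.

### Ablation ladder

Four arms share one cohort, split and seed: `conventional` (two-class
softmax, no textures, no constraint; score = p₁), `texture` (three-class
softmax; binary score p₁/(p₀+p₁) — the renormalization is a package
convention, as a three-class output has no canonical binary score),
`texture_l2` (adds the constrained head), `texture_l2_lof` (LOF on the
constrained descriptors). Arms train on the training split, select on
validation loss and are evaluated once on the test split. Across seeds
the per-arm *median* of each metric is reported — robust at the default
five seeds.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes,
not MRI physics:

* **Normal class** (default 190 cases): a small pool (3) of smooth
  Gabor-blob archetypes — centred round lesions with narrow parameter
  ranges — shared across cases with additive Gaussian noise
  (sd 0.05) and mild intensity jitter: numerous and compact.
* **Abnormal class** (default 55 cases, 22.4% prevalence): a larger
  archetype pool (12) in which each case redraws its own geometry
  (2–5 blobs, random positions/scales/frequencies): rare and diverse.
* **Paired contrasts**: both images render the same underlying tissue
  field through independent gamma maps, the second inverted —
  correlated but distinct, so two-channel fusion is informative.
* **Texture library** (default 61 images at 128 px, centre-cropped to
  the input size): oriented gratings, band-filtered noise and their
  products — deliberately unlike the cohort archetypes.

Cohort sizes, imbalance, split fractions (60/20/20) and the published
per-subtype split table (151/48/46 totals) mirror the reference
cohort. Default split counts follow largest-remainder rounding of the
fractions per label; the published totals (which are not an exact
60/20/20 rounding of 245) are reproduced via `explicit_counts`.

What passing on synthetic data shows — and does not. The cohorts
reproduce the compact-normal / diverse-abnormal geometry, the
imbalance, and the paired-contrast structure, so they exercise every
pipeline contract and the *ordering* of the ablation arms. They do not
contain MRI noise statistics, scanner variation, partial-volume
effects, or subtle real-lesion morphology; absolute metric values on
synthetic cohorts say nothing about clinical performance.

## Scaled-down benchmark

`default_benchmark_config()` defines the package's end-to-end check:
the full-size synthetic cohort (190/55 at 100 × 100, 60/20/20 split),
`tiny_cnn`, 15 epochs of Adam at 1 × 10⁻³ (a from-scratch learning
rate; 10⁻⁵ is a fine-tuning rate and cannot move a randomly initialized
network in 15 epochs), batch size 1, full augmentation, five seeds, two
arms (`conventional`, `texture_l2_lof`), 500 bootstrap replicates. The
expected outcome, asserted in the acceptance tests, is the ladder's
headline ordering: median test ROC-AUC of the LOF arm ≥ the
conventional arm, and > 0.5.

## Numerical choices and degenerate inputs

* Images are floats in [0, 1] everywhere in memory; 8-bit only at PNG
  I/O (quantization error ≤ 0.5/255 per pixel).
* Resize: bilinear with anti-aliasing on downscale; a same-size resize
  returns the input unchanged. Centre crop uses floor((dim − size)/2)
  offsets and never interpolates.
* Largest-remainder rounding breaks remainder ties toward the earlier
  split (train first).
* No per-image intensity normalization is applied before fusion (the
  `[0, 1]` range is used as-is); window/level handling of real scanner
  data is the caller's responsibility and is deliberately out of scope.
* The L2-constraint scale applies everywhere descriptors appear —
  inside the loss and at LOF time — because the constraint is an
  architectural layer, not a loss-side trick.
* Bootstrap resamples are stratified by class, so both classes are
  always present in a replicate.

## Known limitations

* 2-D single-slice inputs only; no volumetric context.
* No OCSVM or autoencoder comparison arms; no MobileNet/ResNet
  backbones.
* `vgg16_transfer` needs locally supplied pretrained weights to
  reproduce transfer learning; no downloader is included.
* The test-derived Youden threshold inflates sensitivity/specificity
  relative to a prospectively fixed threshold; the report flags it.
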