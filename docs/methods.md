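# Methods

## Problem setting

The package targets single-source domain generalization for 3D image
classification: a classifier is trained on one cohort (the source
domain) and evaluated on cohorts it has never seen (target domains),
whose scans differ by acquisition effects — global intensity calibration,
smooth spatial intensity inhomogeneity ("bias fields"), and noise level —
rather than by the disease signal itself. The guiding hypothesis is that
a model whose spatial evidence is anchored to disease-relevant anatomy
degrades less under such shifts than one free to exploit any correlate in
the training data.

## Architecture

The classifier has three parts, all implemented directly on numpy in
float64 with hand-derived backpropagation (`netcore`):

* **Encoder** — a stack of `conv(3x3x3, same) -> ReLU -> 2x average
  pool` stages with configurable channel widths; input axes must be
  divisible by `2^n_stages`. Parameters are He-initialized from the
  config seed.
* **Attention module** — two parallel 3D convolutions (kernel size
  configurable, default 1x1x1) from the `C` encoder channels to `K`
  class channels: projected features `F'` and attention maps `M`. `M`
  has a **linear** activation so attention is signed and directly
  comparable to signed saliency priors in [-1, 1]; nothing in the
  training objective requires `M` to be positive or normalized. The
  module's output is the element-wise product `F' .* M`.
* **Classifier** — global average pooling: the logit of class k is the
  arithmetic spatial mean of product channel k (mean, not sum, so logits
  are resolution-independent), followed by softmax.

One further initialization choice matters in practice: the attention
convolution's bias starts at 1, so modulation begins at identity
(`M ~ 1`). With both branches near zero at initialization, the product
form otherwise starves early gradients and small-scale training stalls at
chance.

The convolutions are evaluated as k³ shifted slab matmuls on the padded
volume; the same decomposition yields the weight and input gradients.
Input gradients are exposed (`input_gradient`) because the attribution
backend integrates them along a path in input space.

## Objective

* **Weighted cross-entropy.** Class weights are the inverse training
  counts `w_k = 1/n_k` (module `losses`; no renormalization by default,
  with an optional mean-1 rescaling). The trainer uses the mean-1
  rescaled weights so the gradient scale — and therefore a given
  learning rate — does not depend on dataset size. Probabilities are
  clamped at 1e-12 before the log.
* **Alignment loss.** For each sample i and class k, the Euclidean norm
  over voxels of `M_{i,k} - P_k`, summed over i and k; the per-block
  gradient is the unit direction `(M - P)/||M - P||`. A squared-norm
  variant and a mode restricting the sum to each sample's true-class
  channel exist behind flags; the default sums over all K channels. The
  default batch reduction is the mean, keeping gradient scale independent
  of batch size (a sum reduction is available).
* **Combination.** `L = L_WCE + lambda * L_sim`. The package default is
  `lambda = 5e-5`, appropriate when the alignment term is summed over
  full-resolution grids of ~10^6–10^7 voxels; the desk-scale phantom
  study uses `lambda = 1e-3`, chosen once so that `lambda * L_sim` is a
  few percent of the total loss at initialization — the same relative
  weighting, at the phantom's much smaller grid and hence much smaller
  `L_sim` magnitude. Pilots showed that making the alignment term
  dominant (lambda >= 3e-3 at this scale) collapses classification: with
  the attention maps pinned to class-constant priors, the single
  projection convolution cannot carry the discriminative signal alone.

## Saliency priors

Stage 1 trains the baseline with weighted cross-entropy only. Priors are
then computed offline and frozen:

1. run inference on the training split; keep samples whose argmax
   prediction (ties toward the lowest class index) equals the label;
2. attribute each kept sample toward its true class, relative to a
   reference volume;
3. average the signed attributions per class (signed, not magnitudes, so
   positive and negative evidence survive averaging);
4. scale each class prior by its maximum absolute value into [-1, 1]
   (`maxabs`; a raw mode exists), and record the per-class sample counts.

The default attribution backend approximates the Shapley value by a
path integral of input gradients from the reference to the input,
sampled at stratified-jittered path positions (seeded). It is exact for
linear models at any sample count, and its completeness residual
(attributions minus the logit difference) shrinks with the sample count
as ordinary Monte-Carlo error. An exhaustive subset-enumeration backend
(`method="exact"`) provides ground truth for inputs with at most ~14
voxels differing from the reference and is used as the test oracle.

**Reference choice.** The API default is the all-zeros volume. For the
phantom experiments the reference is the training-set mean volume,
passed explicitly: against zeros, attributions are proportional to
`x * grad` and spread over all bright anatomy, whereas against the cohort
mean, `x - ref` isolates what distinguishes the subject — the lesion —
and the class priors concentrate an order of magnitude more strongly
inside the disease regions (in-lesion to out-of-lesion mean |prior|
ratios of ~10–70 vs below 1). Practically, a cohort-mean reference is
the recommended setting whenever a training set is available.

For the alignment loss, priors are trilinearly resampled
(corner-aligned) from input resolution to the attention grid.

## Training protocol

Both stages use Adam at a constant learning rate, a seeded shuffled
cycling sampler (a fixed number of weight updates per epoch can exceed
one pass over a finite dataset), and gradient accumulation: each update
averages per-sample gradients over `accumulation_steps` micro-batches,
which is numerically identical to one large batch (asserted to 1e-5
relative in the tests). The configured default schedule is 60 epochs of
200 updates with micro-batch 2 and 8 accumulation steps (effective batch
16); the phantom studies scale this down to 12 epochs of 20 updates at
the same effective batch. Checkpoint selection is by validation macro F1
when a validation split is provided. The stage-2 model is freshly
initialized from its own seed, independent of the baseline's.

Augmentation (optional, applied per micro-batch sample): gamma contrast
jitter, a smooth multiplicative bias field, random crop with trilinear
upsampling back to the input grid — each firing with a configurable
probability — followed by deterministic min–max intensity scaling to
[0, 1]. Mixup (convex combinations of example pairs and their one-hot
labels with Beta(alpha, alpha) weights, default alpha 0.2 when enabled)
is provided as a comparison baseline; pairs are formed by a random
single-cycle permutation so no sample mixes with itself. Mixed soft
targets enter the weighted cross-entropy as
`-sum_k w_k y_k log y_hat_k`.

Stratified k-fold cross-validation uses scikit-learn's stratified
partition into k blocks; for run f the test block(s) start at fold f,
validation block(s) follow, and the remainder trains — with k = 5 and a
3:1:1 ratio this gives the 60/20/20 rotation. Fold metrics aggregate as
mean ± population standard deviation.

## Evaluation metrics

Confusion matrices are indexed [predicted][true]. Macro F1 averages the
per-class harmonic mean of precision and recall, with degenerate classes
contributing 0; the multiclass MCC is computed from the per-class
prediction counts `p_k`, true counts `t_k`, correct total `c` and grand
total `s`, and defined as 0 when either factor under the square root
vanishes (e.g. all predictions in one class). Both metrics are
transpose-invariant — macro F1 because swapping precision and recall
leaves the harmonic mean unchanged, MCC by symmetry of its formula — so
the choice of row convention cannot silently corrupt either. Per-domain
metric rows are complemented by an unweighted mean over target domains.

## Region-level pathology validation

Attention is aggregated per parcellation region as the region sum divided
by the region's voxel count. When the attention grid differs from the
atlas grid, the default is to downsample the atlas by nearest neighbour
(preserving label identity) rather than interpolate the attention twice.
Spearman rank correlation (average ranks on ties) is computed across
subjects between region score and ordinal grade, per region; constant
vectors yield an undefined correlation reported as missing (never 0),
and regions with fewer than 3 overlapping subjects are omitted.

**Which map is scored.** The phantom study correlates grades against the
disease-class channel of the attention module's *output* (`F' .* M`, the
class-evidence map) rather than raw `M`. Raw `M`'s response to disease
severity has an arbitrary sign per trained model — at desk scale the
learned weights can encode lesion evidence with either polarity, and the
sign of the correlation flips between seeds accordingly — whereas the
evidence channel is sign-anchored by the classification objective itself:
its spatial mean is the disease logit, which must increase with disease.
Signed raw-`M` aggregation remains the `region_attention_scores` default
for API compatibility, and an absolute-value mode exists behind a flag.

## The phantom generator

Synthetic cohorts emulate, at desk scale, the structure of a
multi-cohort MRI study (`phantom`):

* an ellipsoidal "brain" mask partitioned into contiguous regions by
  seeded Voronoi growth from random interior points (label 0 is
  background);
* per-subject base anatomy as a smooth seeded random field on the mask;
* disease classes defined by designated atlas regions whose intensity is
  *reduced* by `effect_size * severity` (hypointensity, mimicking
  atrophy-like signal loss), with per-subject latent severity drawn from
  upward-stratified class-conditional bands (class 0 is the control
  class at severity 0; with K classes, diseased class c draws uniformly
  from the band centred at c/(K-1));
* per-domain acquisition effects applied in order — global intensity
  scale, smooth multiplicative bias field, additive Gaussian noise —
  then min–max scaling to [0, 1];
* ordinal pathology grades per region as equal-width quartile binning of
  `severity x involvement` into {0,1,2,3}, with optional seeded ±1
  ordinal noise; with zero noise the grade is a deterministic monotone
  function of severity in involved regions and 0 elsewhere.

Everything is a pure function of the spec and its seed.

What the phantom does *not* emulate: anatomical realism, registration
error, partial-volume effects, class-dependent global atrophy patterns,
longitudinal change, or site effects beyond intensity transforms.
Passing the phantom studies therefore demonstrates that the pipeline's
mechanics behave as designed — priors localize the generative lesion,
alignment is optimizable, region evidence tracks generative severity —
not that the method improves transfer on real MRI.

## The frozen study (`ddgen.study`)

`run_study_seed` fixes the end-to-end conditions: 16³ grid, 6 atlas
regions with classes 1/2 lesioning the two largest, effect size 0.5,
12 subjects per class per domain; one clean source domain (noise 0.02)
and two targets — intensity scale 1.6 with mild bias, and a strong
(amplitude 0.8) very smooth (length-scale 8 voxels) bias field, both with
noise 0.03. The smooth-bias target is deliberate: a very smooth
multiplicative field corrupts regional and global intensity statistics
while approximately preserving local contrast, which is exactly the
regime where evidence anchored to the lesion neighbourhood should
transfer better than diffuse evidence. Training uses a single-stage
encoder of width 8 (attention at 8³ — coarse enough to be fast, fine
enough that resampled priors retain the lesion's location), a stratified
3:1:1 split of the source, augmentation, 12 x 20 updates at effective
batch 16, learning rate 1e-2, and lambda 1e-3.

Measured on seeds 1–3, the guided model's mean target accuracy exceeds
the baseline's (0.551 vs 0.537) and the mean pathology correlation in
lesioned regions is 0.82. The transfer margin is real but small and
seed-noisy at this scale — consistent with the from-scratch setting,
where prior guidance acts as a regularizer on a model with little
capacity to spare; with the alignment term made dominant (lambda ~ 1)
the similarity loss is driven down monotonically, confirming the
optimization path, at the cost of classification accuracy.

## Numerical choices and edge cases

* float64 throughout; deterministic given seeds (no threading
  nondeterminism in the update path).
* log-probability floor 1e-12; alignment gradient defined as 0 at
  `M = P`; MCC 0 on degenerate denominators; macro F1 contribution 0 for
  zero-support classes; Spearman undefined (missing) on constant input.
* min–max scaling maps constant volumes to zero.
* argmax ties (prediction, prior sample selection) resolve to the lowest
  class index.
* trilinear resampling is corner-aligned, so identity targets are
  bit-exact and constants are preserved.
* one global seed fans out to per-stage streams via a CRC-based hash
  (`io.stage_seed`), keeping each stage independently reproducible.

## Known limitations

* The encoder is a generic conv-pool stack, not a large pretrained 3D
  backbone; pretrained weights can be loaded through the checkpoint
  mechanism but none ship with the package. The paper-scale benefit of
  prior guidance on top of strong pretrained features is therefore out
  of reach of the desk-scale studies.
* The expected-gradients backend assumes the model is differentiable
  almost everywhere along the reference-input path.
* Grades in the phantom derive from a single latent severity, so
  region-wise grade profiles are more correlated than real
  neuropathology.
* Attention supervision couples every class channel to a class-constant
  prior; with very small models and binding lambda this provably removes
  discriminative capacity (see above) — lambda must stay in the gentle
  regime.
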