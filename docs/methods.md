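# Methods

`vfmgl` builds lightweight "expert" imaging models for multi-center
settings in two stages: a knowledge-transfer stage that distills general
visual representations from a large frozen vision-transformer teacher into
a small convolutional student and freezes the layers that received the
most of that knowledge, and a federated stage in which centers exchange
only model parameters, select low-heterogeneity training batches, and
distill common knowledge from the aggregated shared model. This note
records the model assumptions, the defaults and why they are what they
are, and the places where the design was genuinely open.

## Numerical substrate

All networks run on a small reverse-mode automatic-differentiation engine
over float64 numpy arrays (`vfmgl.nn`). Convolution is im2col plus matrix
product; max-pooling stores argmax indices; bilinear resizing is a fixed
linear map applied along the two trailing axes, so its adjoint is exact.
Gradients are verified against central finite differences in the test
suite. Float64 keeps gradient checks at 1e-6 tolerance; at desk scale the
speed cost is irrelevant.

The zoo contains the standard 18-layer residual classifier and a u-shaped
encoder/decoder segmenter as students (both with a `width` knob scaling
all channel counts; width 64 is the standard architecture, widths 2–8 are
the desk-scale variants used in experiments), and two plain ViT encoders
as teachers: the ViT-B/14 geometry (768 dim, 12 blocks, 12 heads, patch
14) matching the foundation-model teacher, and a "tiny-vit" (96 dim, 4
blocks, patch 8) so the full transfer pipeline runs in seconds with random
weights. Teachers are frozen at construction; feature extraction through
them never builds a graph.

### Profiling convention

Parameter counts and MACs are computed analytically from the architecture
description, not from instantiated weights. MACs are module-level — one
multiply–accumulate per output element of convolution, dense and
normalization modules — with the attention QKᵀ and attention·V products
excluded, as most architecture profilers report them. Under this
convention one forward pass of the ViT-B/14 teacher at 224×224×3 costs
21.95 G MACs against 1.82 G for the residual-18 student, a 1:12 compute
ratio at a 1:8 parameter ratio (85.7 M vs 11.2 M parameters); the teacher
resolution of 224 follows from all inputs being resized to 224×224×3 and
the patch size dividing it exactly.

## Stage 1 — heterogeneous-model knowledge transfer

Transfer channels are the full bipartite set of teacher blocks × student
stages (block granularity: four residual stages, the nine u-net blocks,
the transformer blocks). Finer granularity would explode the pair space
with no benefit at these depths. Each channel has a learnable 1×1
projection from token space to the student's channel count; teacher
tokens (class token excluded) are reshaped to their spatial grid,
projected, and bilinearly resized to the student map.

The transfer loss is the weight-of-pair–weighted mean-squared difference
between channel-normalized maps. Channel normalization is zero-mean/
unit-variance per channel with a stabilizer *relative* to the mean channel
variance, which makes the loss exactly invariant to a common positive
rescaling of a pair's maps and well defined on all-constant maps.

### Meta-learned transfer weights

Raw transfer weights are emitted by a two-layer perceptron from per-pair
statistics (mean absolute activation of each side, task-loss running
mean), passed through a softplus scaled so a zero-initialized output head
emits exactly the uniform weight 1/|teacher blocks|. Raw weights are free
non-negative magnitudes — against an unhelpful teacher the total transfer
strength can decay toward zero — while the per-student-layer *normalized*
weights form a probability vector, which is what criticality scoring and
the serialized plan report.

The meta-objective is a first-order one-step lookahead: simulate a student
step on task + transfer loss, evaluate the task loss on a held-out
mini-batch, and differentiate that validation loss into the weights. To
first order, ∂L_val/∂w_p = −lr·(∇L_val · ∇L_p); the per-pair directional
derivatives are obtained by central finite differences of all per-pair
losses along the validation-gradient direction, so every pair shares two
extra forward passes instead of needing its own backward pass. A meta
step restores the student's parameters *and* normalization buffers
afterwards — it must be observationally free of side effects on the
student, otherwise comparisons between meta-learned and uniform weights
are confounded by batch-statistics exposure. The meta optimizer is SGD
with learning rate and weight decay 0.001 and momentum 0.9.

On a separable toy task with an adversarial teacher (a randomly
initialized transformer emitting label-independent features), the mean
raw transfer weight decays over tens of meta-steps and final task
accuracy with meta-learned weights is at least that of uniform weights —
the negative-transfer-suppression behaviour the mechanism exists for.
Early in training, before the task is fit, the alignment signal between
transfer and validation gradients is weakly positive even for a random
teacher; suppression emerges as the student approaches the task/transfer
equilibrium, which is why the behavioural experiment trains to near-fit
before reading out the trend.

### Criticality and freezing

A student layer's criticality is its share of total raw transfer-weight
mass; scores sum to one. The top half of layers by score (ties toward the
earlier layer) is frozen — the fraction is configurable, half being a
neutral default in the absence of stronger guidance. Freezing is enforced
twice: frozen parameters are excluded from the optimizer, and broadcasts
from the server never overwrite them, so bit-identity across the entire
second stage is guaranteed and tested by checksum.

## Stage 2 — federated rounds with DDBL and distillation

One communication round broadcasts the shared parameters to every client
(skipping frozen layers), runs one local pass, and aggregates the
returned parameters by a weighted element-wise mean with weights
proportional to the centers' training-set sizes (the usual choice when
nothing else is stated). Aggregation covers normalization buffers as well
as weights. The server log records only array names and shapes; no tensor
with image dimensions ever reaches it.

All clients share one parameter initialization. Element-wise parameter
averaging is only meaningful between models with a common origin;
averaging independently initialized networks destroys the shared model's
function (internal units are permuted differently), which at toy scale is
immediately visible as a consensus model that is wrong everywhere.

### Batch scoring and selection

A batch's heterogeneity is the per-sample-averaged KL divergence between
the local and shared models' temperature-softened prediction
distributions (pixelwise Bernoulli distributions for segmentation,
averaged over the mask plane), KL(local ‖ shared), evaluated with both
models in evaluation mode so scoring is deterministic. It is exactly zero
when the two models are parameter-identical. The change against the
previous scoring pass is tracked as the divergence rate. Selection keeps
the lowest-divergence fraction (default 0.7), ranking by divergence with
|rate| and then batch id as tie-breaks. Softening temperature 2 and
distillation mixing α = 0.5 are conventional distillation settings; all
three are exposed in configuration.

The distillation loss is α·task + (1−α)·T²·KL(soft shared ‖ soft
student), with cross-entropy (classification) or soft Dice
(segmentation) as the task term, applied only to non-frozen parameters.

### What makes the deduction signal visible

The divergence statistic compares two *functions* at the batch's inputs,
so it only carries information once the local model has actually adapted
to its data while the shared model has not. The planted-outlier
experiment therefore (i) gives each center its own patient population
(independent structural draws), (ii) runs a warm-up phase of gentle
federated averaging until the consensus fits the common data, and (iii)
lets each local model fit its own batches to near-memorization within a
scored round. Two empirical failure modes of the raw statistic are worth
recording. First, an extreme corruption that saturates pixel values (a
large additive shift clipped to the valid range) washes out image
structure; both models then collapse to the same confident output and the
corrupted batch scores *low*. The planted artifact is therefore a
channel-asymmetric shift (one channel up, one down) that stays
informative. Second, a single scoring pass is noisy; ranking by the mean
divergence over the scored rounds — recoverable from the score and its
rate — combines magnitude with its trajectory and stabilizes the
exclusion. Both points are visible in the round-level audit CSVs the
pipeline writes.

### The three-arm ablation study

The canned ablation compares Stage-1-only models, federated rounds with
distillation, and federated rounds with distillation plus batch
selection, all trained on federations whose training streams contain a
20 % clustered decision-corrupting artifact run (contrast inversion) per
center, and all evaluated on quality-controlled artifact-free test
cohorts from the same centers — mirroring how clinical enrollment
excludes poor-quality images while live training streams still contain
them. The study runs 6 communication rounds with three local passes per
round: a single pass per round (the full-scale convention) leaves local
models so close to the consensus that batch divergences are flat and
selection degenerates to noise at this scale. Across ten seeds the
distillation arm improves the cross-center mean AUC over the Stage-1
models by ≈0.10 in paired seed-median; the additional selection arm sits
within ±0.01 of the distillation arm. At desk scale, corrupted images
with intact labels act much like data augmentation, so excluding them
does not reliably recoup the ~20 % training-data loss — the benefit the
full-scale method reports evidently needs heterogeneity that small
synthetic federations do not reproduce.

## Synthetic multi-center data

Classification images are smooth random backgrounds; positives carry a
bright textured elliptical blob (radius 15–28 % of the image side,
brightness offset 0.45, sinusoidal texture) — strong enough that a
reduced-width student learns it from a few dozen samples, the point being
to exercise the pipeline rather than to challenge it. Segmentation images
render one or more such blobs with exact masks. Center effects are
applied after class rendering: additive intensity shift (±0.15 across
centers by default), contrast gain (0.8–1.25), a small channel rotation,
Gaussian noise (σ 0.02), optional blur (σ 0.6 on alternate centers),
per-image intensity jitter (σ 0.08, protocol drift within a center), and
with probability 0.1 an extreme artifact shift (0.35, signed away from
the center's own bias so it cannot saturate) — the corrupted acquisitions
batch-level deduction is meant to drop. Labels are exactly balanced to
the configured prevalence; everything is a pure function of (config,
seed).

By default all centers share one structural random stream, so with zero
effects two centers are pixel-identical and any cross-center difference
is attributable to the planted effects; experiments that model distinct
patient populations set `distinct_centers`. Splits are stratified by
label with largest-remainder allocation (so 10 samples at 6:4 give
exactly 6/4, and 100 at 0.64/0.16/0.20 give 64/16/20).

What the generator does not emulate: anatomical structure, label noise,
class-conditional acquisition differences, scanner-specific texture, or
any correlation between patient demographics and image content. Passing
behavioural tests on this generator shows the mechanisms respond to
planted heterogeneity as designed; it does not show clinical performance.

## Evaluation

AUC is the Mann–Whitney U statistic normalized by n₊n₋ with ties counted
one half; it equals the trapezoidal area under the empirical ROC, and the
test suite asserts the two computations agree to 1e−12. Threshold metrics
use the training-set Youden cutoff when none is given; ratios with empty
denominators are reported as NaN, never as zero. Decision curves use the
standard net benefit TP/n − FP/n·p_t/(1−p_t) on a 0.01–0.99 grid.
Segmentation reports Dice, IoU (with both-empty pairs defined as perfect
agreement), pixelwise sensitivity/specificity/PPV, and ASSD computed from
4-adjacency boundaries via exact Euclidean distance transforms; when
exactly one mask is empty ASSD returns the image diagonal — finite, so
center averages stay usable, and maximally pessimistic.

Because batch normalization's running averages lag the weights they
normalize, models are passed through a one-batch statistics recalibration
on their training images before eval-mode metrics are computed. Ranking
metrics are hardly affected; threshold metrics are meaningless without
it at short training horizons.

Center similarity for external model selection scores both datasets
batch-wise under one (local, shared) model pair and correlates the two
sorted divergence profiles interpolated to a common length (a
quantile–quantile Pearson correlation). Raw profile order across two
different datasets is arbitrary, so the distributional comparison is the
meaningful one; `profile_correlation` exposes the plain Pearson step
separately. Higher similarity means the external center's heterogeneity
resembles the reference center's, and the local model of the
most-similar center is the better pick for external prediction.

## Interpretability

Activation maps are gradient-weighted class activation maps of a chosen
hookable stage (default: the last non-frozen one), computed in evaluation
mode — a single image has no meaningful batch statistics — rectified,
max-normalized and bilinearly upsampled. At 32×32 the last stage is 1×1
spatial, so localization analyses use an earlier stage with spatial
extent.

The adaptive/common knowledge analysis applies every center's local model
to one common sample set, giving row-aligned feature matrices. mRMR
filtering uses equal-frequency 10-bin discretization, mutual information
with the label as relevance, and the difference criterion (relevance −
mean redundancy), ties to the lower feature index. A unit is *adaptive*
for a center when it has high maximal |r| against the other units of the
same center's model, and *common* when the same unit index correlates
across all center pairs (features are aligned by penultimate-unit index,
all centers sharing one architecture); the top quarter by each criterion
is tagged by default. Whether "highest correlation" should be signed is
not determinable from the statement of the method; absolute correlation
is used throughout. PCA embeddings fix signs by making each component's
largest-magnitude loading positive.

## Experiment scale and defaults

The published per-use-case training settings are preserved verbatim in
the `uc1`–`uc4` presets (use case 1: 20 epochs, lr 1e−4, weight decay
1e−4, batch 25, SGD momentum 0.9, 6:4 split at seed 42; use case 2:
10/0.01/0.001/32; use cases 3–4: Dice loss, 100 epochs, Adam lr 1e−4 and
SGD lr 1e−3, batches 3 and 2, with 20 % test and 4:1 train:val splits).
Desk-scale presets run three centers of 48–80 samples at 32×64 px with
width-2/4 students and the tiny-vit teacher; behavioural experiments use
ten seeds and report seed medians. These sizes are chosen so each
behavioural claim is exercised by tens of full training runs in minutes
while remaining large enough for the planted effects to dominate seed
noise.

## Known limitations

- The meta-network's inputs and architecture are a documented stand-in
  realizing the stated contract (weights respond to task-performance
  changes); richer per-pair statistics are possible.
- Criticality uses transfer-weight mass only, not gradient sensitivity.
- The divergence statistic's saturation failure mode (above) means
  batch-level deduction cannot flag corruptions that destroy image
  content; sample-level deduction is out of scope.
- Aggregation is synchronous with full participation; no client sampling,
  dropout, or secure aggregation.
- The exact similarity statistic behind external model selection is a
  design choice (quantile-profile correlation); only its ordering
  semantics are testable.
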