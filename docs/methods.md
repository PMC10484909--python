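# Methods

## Model

The core model is a conditional GAN split across a federation. The central
generator `G` is an encoder–decoder ResNet: a 7×7 stem, two stride-2 3×3
convolutions, a stack of residual blocks, two 3×3 transposed convolutions,
and a 7×7 head squashed by tanh to [−1, 1]. All non-residual convolutions
are followed by batch normalization and ReLU. The full-scale default has
nine residual blocks at base width 64; the toy scale used by the tests has
one or two blocks at width 8–16. Stochasticity comes from dropout inside
the residual blocks (rate 0.5), active during training *and* inference —
the generator has no latent input, so inference-time dropout is what makes
it a one-to-many sampler of the conditional distribution.

Each center holds one PatchGAN discriminator per available modality (or a
single multi-channel discriminator: base mode, and a config switch in
multimodal mode). Discriminators are fully convolutional stacks of 4×4
convolutions with LeakyReLU(0.2) and batch normalization (none on the first
and last layers), sigmoid-squashed to a per-patch score map. The
full-scale default (widths 64-128-256-512, strides 2-2-2-1-1) has a 70×70
receptive field, computed exactly by the recurrence `r ← r + (k−1)·jump`,
`jump ← jump·s`; toy specs compute theirs the same way.

### Losses and the distributed update

Per round, each center draws a mask batch from its own data (uniform with
replacement, matching a uniform per-center sampling distribution), receives
synthetic images for those masks, updates its discriminator(s) once on the
standard cross-entropy objective, and returns the gradient of its local
generator loss — adversarial `log(1−D)` plus λ₁·L1 plus λ₂·perceptual —
with respect to the synthetic batch, together with the scalar loss values.
The server scales each packet by `π_j / (N Σπ)` (π renormalized to sum to
one; the 1/N prefactor is kept as printed, with a `strict_eq5` switch to
drop it) and backpropagates through its cached forward pass, then takes one
Adam step (lr 2·10⁻⁴ full scale, β₁ = 0.5). λ₁ = 100 and λ₂ = 10 follow
image-to-image translation convention; the phantom benchmark runs with
λ₂ = 0 because at 16×16 the L1 term already pins the conditional mean and a
perceptual term adds cost without changing any tested behavior. Log
arguments are clamped at 10⁻⁸, the only deviation from the idealized
formulas.

Gradient correctness is established two ways: every layer's backward pass
is verified against central finite differences, and the aggregated
per-center gradient is verified against numerical differentiation of the
π-weighted sum of local losses on a toy batch.

### Multi-modality and missing modalities

With `c` modalities the generator emits `c` channels and the per-center loss
sums Eq.-4-style terms over the center's available set `C_j` only; centers
simply deploy `|C_j|` discriminators. Because discriminators for a given
modality exist at *some* center, the generator learns all channels and can
complete missing ones at sampling time.

### Continual mode

Tasks are visited in order; at task `t` the generator warm-starts from the
task-`t−1` best checkpoint, old cohorts are retired (their real data and
discriminators become inaccessible — enforced, not just unused), and the
update adds `λ·mean((G_t(x) − G_{t−1}(x))²)` on masks retained from earlier
tasks, with `G_{t−1}` frozen and its dropout disabled so the anchor is
deterministic. The squared norm is implemented as a per-pixel mean so its
scale is resolution-independent; consequently a reminding weight comparable
to the digesting reconstruction weight (λ = 100 when λ₁ = 100) restores the
gradient balance that a weight of order one would have under a
sum-over-pixels reading. The benchmark uses λ = 100; λ = 0 is the
fine-tuning ablation.

### Dist-FID

FID is `‖μ₁−μ₂‖² + Tr(σ₁+σ₂−2√(σ₁σ₂))` on Gaussian fits to extracted
features (covariance divisor n−1). The matrix square root uses the
symmetric PSD branch via eigendecomposition of `σ₁^½ σ₂ σ₁^½`, clipping
small negative eigenvalues from roundoff. Dist-FID is the dataset-size-
weighted sum of per-center FIDs against the synthetic set; per-center
statistics are transmitted once before training. In missing-modality
federations, statistics are computed channel-wise with a shared
single-channel extractor and a center's term is the mean over its available
modalities, so all comparisons happen in a common feature space.

The feature extractor is pluggable. The default is a fixed-seed
random-weight convolutional pyramid (two stride-2 conv+ReLU stages,
per-channel spatial mean and standard deviation pooling). Random
convolutional features are deterministic, need no downloads, and preserve
the intensity/texture statistics that matter at phantom scale; an
ImageNet-pretrained extractor can be plugged in through the same interface
for real data. The same extractor family serves the perceptual loss and
the membership-attack features.

## Phantom data generator

Each sample is a label mask (one random ellipse per foreground class,
later classes painted over earlier ones, fully occluded classes repainted)
rendered to images by a per-(class, modality) intensity table, then
per-center affine transform (`intensity_scale`, `intensity_shift`), then
i.i.d. Gaussian noise (optional blur), clipped to [0, 1]. Per-sample seeds
derive from (center seed, sample index) by splitmix64 mixing, so centers
are independent reproducible streams; regeneration from a manifest is
bit-exact. Masks are stored as indexed PNG, images as 8-bit PNG plus a
lossless NPZ archive; training consumes the lossless form mapped to
[−1, 1].

What it emulates: per-center intensity shifts/scales (scanner/protocol
differences), noise, unequal center sizes, misaligned modality subsets,
temporal cohorts. What it does not: realistic anatomy, 3-D structure,
spatially correlated noise, resolution differences (a downscale–upscale
option exists but is off by default), or registration error. Passing tests
therefore demonstrate correctness of the machinery and the *direction* of
the paper-style effects under controlled heterogeneity, not clinical-grade
image realism.

## Downstream evaluation

The segmenter is a small U-Net (two resolution levels, width 8 by default,
config-exposed) trained with Adam at lr 0.01, cross-entropy plus soft Dice
(CE alone and BCE are options), a 20 % validation holdout (minimum one
sample; below five samples training refuses), and best-validation-Dice
checkpoint selection.

Metric conventions, fixed because the formulas do not pin them down:
boundaries are foreground pixels with a background 4-neighbor (outside the
image counts as background); distances are Euclidean between pixel centers;
the 95th percentile interpolates linearly over sorted directed distances;
HD95 is the max of the two directed 95th percentiles; both-empty Dice is 1;
empty-mask boundary metrics are reported as missing (NaN) and skipped in
aggregates; reported standard deviations use divisor n. AJI processes
ground-truth objects in ascending label order, greedily consuming the
unused segmented object with maximal Jaccard (ties to the lower label);
unconsumed segmented objects enter the denominator. All four metrics are
tested for exact agreement with exhaustive per-pixel brute-force oracles.

## Membership-inference harness

Features per real image are normalized RMSE (RMSE divided by the real
image's intensity range) and perceptual distance (1 − cosine of extractor
features). Pool setting: both metrics against every synthetic image are
min–max normalized over the pool and summed; the argmin is the match and
the matched pair's *raw* metrics are the classifier features. API setting:
the real image's mask goes to the generator and the returned image is
compared directly. Linear and RBF SVMs (C = 1, RBF bandwidth by the median
heuristic on training distances) report F1/recall/precision/AUC.

## Benchmark study conditions

Fixed in `distsynth.benchmark` (chosen once as a scaled-down federation a
desk CPU can train; sizes below are what the tests and the acceptance
script run):

- **Heterogeneous federation**: 16×16 images, 2 classes (background 0.1,
  classes 0.45/0.8), noise σ 0.04; centers A (n=20, shift −0.15),
  B (n=6, no shift), C (n=20, shift +0.15); test 10 per center from fresh
  seeds. Intensity shifts of ±0.15 against a 0.35 class separation make a
  single-center model fail on the opposite extreme, and the small middle
  center is data-starved — so no single center stands in for the
  federation.
- **Training**: width-8 generator with one residual block, width-8 toy
  PatchGAN, batch 4, Adam lr 10⁻³ (scaled up from the full-scale 2·10⁻⁴ for
  the much smaller model), 120–150 epochs, Dist-FID every 10–15 epochs on
  48 synthetic samples. The model-selection consistency experiment instead
  runs at the full-scale lr 2·10⁻⁴ with evaluations every 5 of 80 epochs on
  96 samples: checkpoint selection is only informative while the score
  still moves, and the slower schedule spreads the convergence valley
  across the evaluation grid.
- **Misaligned modalities**: two modalities where only modality 1 separates
  the classes (0.35 vs 0.75; both 0.6 in modality 0); center A (n=20) holds
  only modality 0, center B (n=20) only modality 1 — no complete real
  sample exists, which is precisely when zero-filling is harmful.
- **Continual**: two single-center tasks (n=16 each) with shifts −0.15 then
  +0.15, 80 epochs per task.
- **Membership inference**: standard regime trains on 20 members (120
  epochs, dropout on) vs 20 non-members; the overfit stress test trains a
  dropout-free generator for 600 epochs on 4 samples; attacks use the API
  setting with a 50/50 train/test split; the null calibration uses 2000
  feature-free coin-flip labels.
- **Synthetic databases**: multiplier 2 over the pooled real masks, with
  scale [0.9, 1.1], shift ±10 %, horizontal flips p=0.5, rotation ±10°.

Stochastic comparisons (benefit of the synthetic database, argmin
agreement, continual retention, privacy regimes) are run over three fixed
seeds and aggregated as sign tests.

## Numerical choices and degenerate inputs

Float64 throughout the layer library; Adam ε 10⁻⁸; batch-norm ε 10⁻⁵ with
momentum 0.1 running statistics (evaluation passes never mutate them);
gradient packets are rejected if non-finite; training aborts on non-finite
losses; Dist-FID ties in checkpoint selection break to the earliest epoch;
`n_classes = 0` phantoms produce pure-background masks; centers must
jointly cover every modality or federation validation fails.

## Known limitations

Single-threaded numpy networks limit practical scale to small images and
slim models — the architecture contracts, not the throughput, are the
point. In-process transport is the only built-in channel (the message
contract is the interface; sockets would slot behind it). The downstream
classifier option is a loss switch (BCE) rather than a separate
architecture. No differential privacy, secure aggregation, or asynchronous
federation.
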