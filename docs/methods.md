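# Methods

## Model

Each of T topics pairs a spatial probability distribution over brain
locations with a multinomial distribution over word types. Three spatial
families are supported: one Gaussian per topic (R = 1), a free two-component
Gaussian mixture (R = 2), and a two-component mixture whose means are
constrained to mirror across x = 0 (`symmetric=True`). Documents are
generated as follows:

1. θ_d ~ Dirichlet(α·1_T) — the document's topic mixture over peaks;
2. each peak: topic y ~ Cat(θ_d), subregion r ~ Cat(π_y) with
   π_t ~ Dirichlet(δ·1_R), coordinate x ~ N(μ_{yr}, diag σ²_{yr});
3. each word token: topic z with p(z = t | d) = (N^x_{dt} + γ)/(N^x_d + T·γ)
   — proportional to the document's realized peak-topic counts — and word
   w ~ Cat(φ_z) with φ_t ~ Dirichlet(β·1_W).

Step 3 is the correspondence device: words can only be emitted from topics
the document actually drew activations from (up to the γ smoothing), so the
fitted word and spatial distributions of a topic must co-occur across the
corpus.

### Collapsed joint

All multinomial parameters (θ, φ, π) are integrated out analytically,
giving a joint over assignments with four Dirichlet-multinomial /
correspondence factors plus the Gaussian likelihood at the current
point-estimated spatial parameters:

* word emission: per-topic Dirichlet-multinomial with concentration β;
* peak-topic choice: per-document Dirichlet-multinomial with α;
* subregion choice: per-topic Dirichlet-multinomial with δ;
* word-topic correspondence: Π_d Π_t (N^x_{dt} + γ)^{N^z_{dt}} /
  (N^x_d + T·γ)^{N^z_d};
* spatial: Σ_peaks log N(x; μ_{yc}, σ_{yc}).

`log_joint` evaluates exactly this expression, and both Gibbs conditionals
are exact ratios of it over candidate assignments — the test suite pins
this equivalence to 1e−10 and additionally checks, on a corpus small enough
to enumerate every assignment configuration, that 50,000 sweeps visit
states with the enumerated posterior frequencies (total variation < 0.01
observed, asserted < 0.05). That enumeration check holds the spatial
parameters fixed: with the interleaved point-estimate updates enabled, the
chain is not stationary with respect to any single fixed joint, so the
check is only well-posed with `update_spatial=False`.

### Inference

Collapsed Gibbs sweeps visit documents in corpus order, word tokens before
peaks, resampling each token's topic and each peak's (topic, subregion)
pair jointly from the T×R table; spatial parameters are then re-estimated.
Gaussian parameters are point-estimated rather than sampled: per
(topic, subregion), the mean and diagonal sample variance of assigned
peaks. In symmetric mode, left-subregion peaks are reflected across x = 0
and pooled with right-subregion peaks; a single pooled mean/variance is
mirrored into the two components, so the mirror constraint holds to
machine precision after every update and the two components share a
covariance (the symmetry constraint binds the means; sharing variances is
the simplest estimator that keeps the density itself mirror-symmetric).
Per-sweep cost is O(T·(N_W + N_X·R)); the sweep records its exact
candidate-evaluation count, which the tests check for linearity.

**Variance annealing.** During the first 50 sweeps the estimated variances
are floored at a value decaying geometrically from the per-axis variance
of all peaks down to the prior variance (roi_sigma² = 50 mm²). With the
spatial term nearly flat early on, assignments first organize on the word
and correspondence structure; the Gaussians then lock onto their clusters
as the floor tightens. Without this schedule the sampler frequently
freezes in modes where one component spans two activation clusters while
another duplicates a cluster (visibly lower log joint than the recovered
mode). A hard variance floor of 4 mm² per axis prevents collapse onto
duplicated coordinates at any stage.

Initialization is uniform-random over topics (subregions by hemisphere
sign in symmetric mode) and fully determined by the seed; a single RNG
stream drives the whole run and is serialized with the state, so a
checkpointed run resumes bit-identically. There is no burn-in or thinning
machinery: the final state is the deliverable, used MAP-style.

## Hyperparameters

| name | default | meaning |
|---|---|---|
| α | 0.1 | Dirichlet concentration, per-document peak-topic mixture |
| β | 0.01 | Dirichlet concentration, topic-word multinomials |
| γ | 0.01 | correspondence smoothing for word-topic draws |
| δ | 1.0 | Dirichlet concentration, subregion weights |
| roi_sigma | √50 mm | initial/fallback spatial std (variance 50 mm²) |
| smoothing_sigma | 4 mm | extra isotropic kernel when voxelizing topic maps |

These are conventional topic-model magnitudes: sparse document mixtures
(α < 1), near-empirical word distributions (small β), weak correspondence
smoothing (small γ so words track peak counts closely), and an
uninformative subregion prior. All are configuration-exposed and recorded
in model metadata. Voxelization adds smoothing_sigma² to each component's
variance before evaluating densities at masked voxel centers; setting it
to 0 disables the extra kernel and smooths only via the fitted variances.

## Decoding

The fitted artifacts are Φ (W×T, Dirichlet-smoothed posterior means) and
the voxelized maps A (T×V, each row a normalized density over masked
voxels) with their Bayes inversion P_{T×V} under a uniform topic prior.
Text inputs are lowercased and matched against the vocabulary with bigrams
preferred over unigrams, longest match first; token contributions to τ are
summed in sorted-token order so the bag-of-words order invariance is
bit-exact. Discrete coordinates snap to the nearest masked voxel within
6 mm when they fall just outside the mask (ties to the smallest voxel
index); τ is normalized for coordinate inputs, whose word weights are
genuine probabilities. Continuous-image decoding (τ = P_{T×V}·I_V) is
deliberately not normalized and is flagged rank-interpretable only; since
input maps are real-valued (t/z statistics), τ may contain negative
entries there, and a constant shift of the input shifts τ by the column
sums of P_{T×V}.

Seeding runs the decoder twice: the seed's τ (computed under a uniform
prior) is normalized to q and blended linearly, p = (1−s)·uniform + s·q.
Linear blending makes strength 0 exactly uniform and strength 1 exactly
the seed posterior; chaining seeded passes composes but is not idempotent.
Reconstruction fits an image on the rows of A by non-negative least
squares and reports R² = 1 − SS_res/SS_tot about the image mean.

## Synthetic data

The generator runs the generative process forward at known parameters.
The default recovery scenario uses T = 4 symmetric topics with means
pairwise ≥ 30 mm apart and 6 mm per-axis standard deviations, subregion
weights spanning bilateral (0.5) to strongly lateralized (0.8), a W = 40
vocabulary in which each topic owns a 10-word high-probability block (85%
of its mass), 300 documents, and Poisson(10) peaks / Poisson(20) words per
document (floored at 1). Annotated evaluation images are voxelized topic
maps scaled to unit maximum plus Gaussian noise of sd 0.1 (10% of peak
amplitude), annotated with the generating topic's top word. Synthetic
maps live on an 8 mm whole-head grid covering MNI extents to keep V small.

What this emulates — and what it does not: documents mixing word tokens
and peaks through a shared topic structure, hemispheric asymmetry, and
map-level noise. It does not emulate Neurosynth's term co-occurrence
statistics, publication bias, coordinate-extraction errors, or the long
tail of rare terms; passing recovery tests demonstrates correctness of
the implementation under the model's own assumptions, not robustness to
real-data misspecification.

## Evaluation harness

Decoder evaluation ranks a candidate term list (ordered by document
frequency in the training corpus) by decoded weight per image, with
average ranks on ties, and locates each annotation in that ranking.
The permutation null shuffles the image↔annotation pairing across images
and recomputes the statistic (median over all annotation ranks); the
empirical p uses +1 smoothing, p = (1 + #{null ≤ observed})/(1 + n_perm).
Shuffling is across images (not terms within images), the natural
exchangeability for image-level annotations. Topic recovery matches
fitted to true topics by Hungarian assignment on mean subregion-mean
distance and reports per-topic mean error, word-distribution cosine, and
lateralization error.

## Numerical choices and degenerate inputs

* Peak conditionals are computed in log space with max-subtraction;
  Gaussian densities of every peak under every component are cached once
  per sweep.
* Empty subregions keep their previous mean and fall back to the prior
  variance (logged); voxels with zero density under all topics get a
  uniform topic posterior column (logged).
* Documents with zero peaks or zero words after vocabulary filtering are
  dropped at load time with a logged warning: the word law conditions on
  peak-topic counts, so a peak-free document has no defined word
  likelihood. Peaks are never snapped to the mask during training —
  spatial distributions are continuous in mm; the mask matters only when
  voxelizing.
* A peak at exactly x = 0 may start in either subregion (random tie); the
  sampler is free to reassign it.
* Maps are written as float32 NIfTI; round trips are bit-exact at that
  precision.

## Problem sizes

The shipped experiments (test suite and `scripts/acceptance.py`) use the
default recovery scenario: 300 documents, ≈3,000 peaks, ≈6,000 word
tokens, 500 sweeps, ≈15,000 voxels, 50 evaluation images, 1,000
permutations. These sizes were chosen so the full loop — generation,
training, decoding, evaluation — runs in minutes on one CPU while leaving
the recovery task unambiguous: failures at this scale indicate bugs, not
ambiguity.

## Known limitations

* Diagonal covariances only; full covariances are not needed for any of
  the supported analyses and destabilize estimation at small counts.
* Gaussian parameters are estimated, not sampled; the sampler is exact
  for the collapsed discrete state conditional on those estimates, and the
  oracle-equivalence tests pin exactly that contract.
* Continuous-image decoding has no absolute probabilistic interpretation;
  only rankings are meaningful. Obtaining calibrated probabilities would
  require training on whole-brain image corpora rather than
  coordinate-based data.
* Topic labels are exchangeable: fitted topic indices are a permutation
  of any generating labels, and all recovery metrics match topics first.
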