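# Methods

## Scope and data model

`rtspect` decodes a categorical response-speed label (fast / medium /
slow) from single-epoch spatial-spectral EEG features and then quantifies
which electrodes and frequency bands the decoder relied on. The in-memory
contracts are: a `TrialSet` (trials × channels × time in µV, with per-trial
RT in ms and subject id), an `AugmentedERPSet` (bootstrap-averaged ERPs
with category and provenance), a topomap image stack (samples × H × W × 3
in [0, 1]), an activation table (one row per sample × electrode × band),
and tabular statistical reports.

## Synthetic generator

No public recording accompanies this design, so the generator is
first-class, tested code that defines the study conditions.

Signal model per trial: 1/f-spectrum Gaussian background noise (flat
below 1 Hz, 10 µV RMS per channel) plus one sinusoid per band at the band
center (α 11 Hz, β 22 Hz, γ 45 Hz) with random phase per trial and
channel. The burst amplitude at electrode e for a trial of category c is
`base_amp(band) × factor(e, band, c) × U(0.8, 1.2)`, with base amplitudes
α 4 µV, β 2.5 µV, γ 1.5 µV. Epochs span −200..800 ms at 500 Hz (500
samples); the sampling rate is a declared default, not an inferred one.

RT mixture (ms): fast N(340, 70²), medium N(640, 65²), slow
N(1030, 140²), outlier N(1800, 250²), weights (0.55, 0.27, 0.12, 0.06),
truncated to [100, 2500] by per-component redraw. These values were chosen
once so that the MAP cluster ranges of a fitted 4-component mixture
approximate the fast ≈ 100–504 ms / medium ≈ 506–770 ms / slow ≈
772–1360 ms bands and the ≈ 67/24/9% category imbalance that motivates
rebalancing.

Planted spatial-spectral effect (the ground truth the full chain must
recover): a single ordered left-frontal α effect at FT7, factors fast
3.0 > medium 1.8 > slow 1.0 — a monotone brain-behavior relation at one
electrode and one band. In addition, category-independent **anchors**
(posterior α at O1/OZ/O2 ×2.2 and POZ ×1.8; central β at CZ/FCZ ×2.0;
central γ at CZ ×1.8) reproduce the stable background topography of scalp
rhythms. The anchors matter: each topomap band plane is min-max normalized
per image, so without a stable reference pattern the plane of a
category with no planted effect is near-uniform and normalization
amplifies background noise into spurious whole-plane texture, which the
decoder then exploits in place of the planted effect. A single planted
site (rather than one distinct site per category) keeps the attribution
target unambiguous: with several category-specific sites, any site that
out-powers the anchors changes its plane's per-image maximum, which
rescales every pixel and makes the anchor region itself
class-informative, so saliency mass drifts off the planted sites.

What the generator does **not** emulate: volume-conducted spatial
correlation from cortical sources, ocular/muscle artifacts, non-stationary
bursts, inter-subject topography differences, or any ERP time-locked
transient. Passing tests therefore demonstrate that the pipeline's
machinery recovers planted band-power topography; they do not certify
performance on real recordings.

## RT clustering

Univariate Gaussian mixtures are fitted by EM (scikit-learn, 10 random
restarts per candidate, reg_covar 1e−6) over k = 1..8 crossed with
spherical/diagonal/tied/full covariance structures; the lowest-BIC model
wins, ties broken toward smaller k then by the covariance order listed.
Category mapping for k = 4: the outlier is the smallest-weight component
among those with mean above the grand median (the sparse slow tail);
the remaining components are fast/medium/slow by ascending mean.
Assignment is hard MAP on posterior responsibilities, and outlier-labeled
trials are excluded before augmentation (exclusion order was an open
choice; excluding before pooling keeps pools homogeneous).

## Bootstrap augmentation and eigenspace filter

Per (subject, category) pool, iterate j = 1..n: if the pool holds ≤ r
trials, emit the mean of all remaining trials once and terminate the
pool (if a drop emptied the pool, terminate without emitting); otherwise
emit the mean of r distinct uniformly drawn trials, and every n_α
iterations permanently remove m = max(1, round(r·α_c)) uniformly chosen
trials. Defaults r = 50, α = (0.3, 0.2, 0.1) for fast/medium/slow,
n = 1500, n_α = 10. Emitting the terminal sample once (rather than
repeatedly, as a literal reading of the iteration loop would) avoids
unbounded duplication that would defeat the algorithm's anti-bias purpose.
The closed-form emission count is
`min(n, n_α·⌈(|pool| − r)/m⌉ + [remaining > 0])` for pools larger than r,
and is cross-checked against a discrete-event simulation in the tests.

The filter builds a PCA basis of the centered raw trials (Gram-matrix SVD,
since features ≫ trials), with k defaulting to the smallest component
count explaining 95% of raw-trial variance — a truncated basis is
required, because reconstruction with all components gives identically
zero residual for anything in the raw span. Each augmented sample's
Euclidean reconstruction-error norm is computed and samples within the
[25th, 75th] percentiles of the pooled error distribution are retained
(inclusive bounds, stable order): exactly 50% for continuous distinct
residuals. Percentiles are pooled across categories by default, with the
slice-wise option exposed by filtering the input.

## Spatial-spectral representation

Band powers: Welch PSD per channel (Hann windows of min(256, n_times)
samples, 50% overlap) integrated over α 9–13, β 14–30, γ 31–60 Hz. The
piecewise-linear PSD is integrated exactly over [lo, hi], interpolating at
the band edges, so powers are non-negative and additive over any partition
of a band.

Projection: azimuthal equidistant about the vertex (planar radius = polar
angle), computed from an idealized spherical 10-10 montage constructed
analytically — outer temporal ring at 72° from the vertex with sites every
18° of azimuth, coronal chains spherically interpolated through their
midline electrode, cerebellar CB1/CB2 at 100° below the occipital ring.
The idealization makes left/right homologues exactly mirror-symmetric,
which a digitized head model is not.

Rendering: per band, electrode powers are min-max normalized to [0, 1]
**per image** (preserving within-map spatial contrast, which is what the
decoder and the saliency chain consume), interpolated with a
Clough–Tocher piecewise-cubic scheme on the electrode triangulation,
nearest-neighbor filled between the convex hull and the head-disk edge
(radius 1.02 × the largest projected electrode radius), zeroed outside
the disk, and stacked R = α, G = β, B = γ on a 32×32 grid (row 0 =
anterior). A constant band renders as a uniform 0.5 plane with a warning.
Note two consequences of these choices: per-image normalization removes
absolute power scale (only spatial contrast survives), and nearest-pixel
values match electrode powers only up to the local interpolant gradient
times the half-pixel offset — the consistency oracle in the tests renders
at 256×256 to isolate interpolation fidelity from pixel quantization.

## Decoder

Architecture: n_blocks × [5×5 same-padding convolution (ELU) →
inception-reduction], flatten, FC stack (ELU, dropout after each FC),
3-unit softmax. An inception-reduction block concatenates three stride-2
branches — 3×3 convolution, 1×1 then 3×3 convolution, 3×3 max-pool — each
convolutional branch ⌈filters/3⌉ channels wide with the pool branch
passing its input channels through; spatial size halves (ceil) per block.
The published best configuration (4 blocks of 52/104/156/208 filters, FC
713/1019, dropout 0.47, Adagrad at 0.006, 165 epochs, 25% validation) is
exposed as `published_config()`.

The network, its backward pass, the optimizers (SGD / Adagrad / Adam),
the plateau scheduler (halve after 5 stale epochs, floor 1e−5) and
best-validation-loss checkpointing are implemented directly on numpy
arrays. This keeps the gradient machinery fully inspectable, which the
saliency module requires: guided backpropagation changes the backward
rule of rectifier activations, and GradCAM needs the class-logit gradient
at an interior feature map. Correctness is pinned by finite-difference
gradient checks and a closed-form parameter-count oracle in the tests.
Training is deterministic for a fixed config seed (one generator drives
the split, batching, and dropout). The validation split is stratified by
class; a subject-wise split is available via `groups=`. The loss is
categorical cross-entropy; batch size defaults to 64.

TPE search: after a random startup phase, observed trials are split at
the γ = 0.25 quantile of the objective into good/bad sets; per-dimension
Parzen estimators (Gaussian kernels with nearest-neighbor bandwidths plus
a uniform prior component; smoothed frequencies for choices) define l(x)
and g(x), and each proposal is the best of 20 candidates drawn from l by
the ratio l/g. The decoder space is depth 2–4, base filter width 16–256
(log), FC width 64–1024, dropout 0.2–0.6, learning rate 1e−4..1e−1 (log),
optimizer ∈ {Adagrad, Adam, SGD}; the documented reference budget is 73
trials.

## Saliency quantification

GradCAM uses the last convolutional feature map (the final reduction
block's output — the standard choice maximizing semantic resolution):
channel weights are the spatial mean of the target-logit gradient, the
map is the rectified weighted channel sum, bilinearly upsampled. Guided
backpropagation applies the rectifier rule (pass where forward activation
> 0 and incoming gradient > 0) inside ELU/ReLU layers; activations
without a guided rule fall back to the plain gradient with a warning.
Guided-GradCAM is their elementwise product. The target class defaults to
the decoder's prediction per sample (`target="true"` is exposed).

Activation scores are the mean magnitude of Guided-GradCAM over the 3×3
pixel neighborhood centered at each electrode's pixel (border-truncated),
emitted for all 64 × 3 electrode-band combinations per sample. The 3×3
mean is a declared convention (single-pixel extraction is noisier);
magnitudes are used because the downstream factorial analysis operates on
non-negative scores.

## Statistics

The model is activation ~ electrode × band × category with all
interactions. With the default per-sample random intercept the design is
a split plot — category varies between samples, everything else within —
so the category effect is tested against the samples-within-category
stratum and the within-sample effects against the within residual after
absorbing per-sample means. Fully balanced tables use closed-form sums of
squares; unbalanced tables use a sum-to-zero-coded type-III Wald path
(full-rank OLS fit, per-term quadratic-form F). The two paths agree on
balanced data and the fixed-effects path is cross-checked against
statsmodels in the tests; the three-way interaction's type-I error is
calibrated (within [0.03, 0.07] at nominal 0.05 over 200 null tables).
A full mixed-model (lmer-style) fit was considered and rejected: no
installed fixture provides factorial F tests for a 576-parameter design
at acceptable cost, and on this design the stratified test is the
classical equivalent.

Tukey HSD contrasts compare the three categories within an electrode
and/or band cell using the pooled within-group variance: z = Δmean / SE,
q = |z|·√2, adjusted p from the studentized range with k = 3; the family
is the contrast triple within the queried cell, matching per-cell
reporting rather than a global 64×3 family. Ranking fits a 3-component
univariate GMM (10 restarts) to the 64 electrode means within each
(band, category) slice and names tiers low/relevant/high by ascending
component mean; all-equal inputs are rejected as degenerate.

## Problem sizes and numerical choices

The end-to-end validation chain runs 12 subjects × 300 trials with
bootstrap parameters scaled to the pools that cohort actually produces
(r = 20, n = 120, n_α = 10 — the full-scale defaults assume ~900-trial
subject pools), a single-block 16-filter decoder with one 64-unit FC
layer trained 35 epochs at Adagrad 0.008, and saliency over the held-out
15%. The shallow decoder is deliberate: its class-activation map lives on
a 16×16 feature grid with small receptive fields, which keeps
Guided-GradCAM attribution sharp enough for electrode-level ranking;
deeper stacks decode equally well but smear attribution over regions.
Null calibration uses 8 samples per category per table. Seeds are
explicit everywhere; identical seeds give bit-identical trial sets,
bootstrap draws, training histories and activation tables. Degenerate
inputs fail loudly: all-identical RTs, empty factorial cells (named in
the error), singleton Tukey groups, rank-deficient designs, bands above
the Nyquist frequency, spatial underflow in the decoder (offending block
named).

## Known limitations

- Saliency attribution on weakly trained or very narrow networks can
  collapse for a class (the guided rule can mask every path to a logit
  whose evidence is encoded negatively); the validation chain trains to
  ≥ 80% validation accuracy before interpreting maps, and real analyses
  should do the same.
- Per-image normalization discards absolute band power; analyses needing
  absolute effects should consume `BandpowerMatrix` values directly.
- The split-plot ANOVA treats within-sample rows as exchangeable given
  the sample mean; spatially smooth saliency maps violate this, so
  within-stratum p-values on real maps are anti-conservative and should
  be read as descriptive.
- The pure-numpy decoder is CPU-bound and intended for the small image
  grids used here, not for full-scale training runs.
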