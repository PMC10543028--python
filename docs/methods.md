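# Methods

## The two-step model

`slide2rx` predicts a cancer patient's response to a targeted therapy from an
H&E-stained tumor slide, indirectly, in two steps:

1. **Expression imputation.** A regression model maps slide images to bulk
   tumor mRNA expression. The slide is partitioned into non-overlapping
   512×512-pixel tiles at 20× magnification; tiles that are mostly background
   (more than half of the pixels with Sobel-gradient magnitude below a
   threshold in [10, 20], default 15, computed on the luminance-weighted
   grayscale 0.299 R + 0.587 G + 0.114 B) are discarded; the remainder are
   colour-normalized and resized to 224×224. Each tile becomes a
   2,048-dimensional feature vector through a pluggable backend, compressed
   to 512 dimensions by an autoencoder with a single 512-neuron bottleneck.
   Genes are partitioned into *tranches* of similar median expression
   (default 4,096 genes per tranche) and each tranche is predicted jointly by
   one multi-task MLP — 512 inputs, one shared 512-node ReLU hidden layer,
   one linear output per gene — so that genes with comparable dynamic range
   share a representation without the loss being dominated by the
   highest-expressed genes. Every tile inherits its slide's bulk expression
   vector as its regression target; tile predictions are averaged to slides
   and slide predictions to patients.

2. **Response scoring.** Given a drug's genetic-interaction partners —
   synthetic-lethal (SL) genes, whose inactivation sensitizes a tumor to
   target inhibition, and synthetic-rescue (SR) genes, whose activation
   compensates for it — the matching score (EMS) summarises how favourable
   the tumor's expression state is for the drug. Expression is
   rank-normalized per gene across the cohort to [0, 1] (average ranks on
   ties, (rank−1)/(n−1)); an SL partner counts as favourable when its rank is
   in the bottom tertile (≤ 1/3), an SR partner when it is below the top
   tertile (< 2/3); EMS is the favourable fraction over partners present in
   the matrix. A patient is *matched* when EMS ≥ 0.54, a fixed decision
   threshold established on independent data and never re-tuned here. The
   drug target's own expression is deliberately never consulted: for
   monoclonal antibodies that component over-weighs one gene whose imputed
   value may be noisy.

Because step 2 needs no response labels, the pipeline can be trained entirely
on public expression-matched slide archives and applied to any drug with a
known partner network.

### The EMS formula is a reconstruction

The published matching score is described only as the "overall activation
state" of the partner genes; its exact activation calls and weighting are not
public. The formula above — tertile activation calls, unweighted fraction —
is this package's own fixed, versioned reading. It preserves the properties
that matter downstream (EMS ∈ [0, 1], monotone in each SL partner's
down-regulation and each SR partner's down-regulation, invariant to monotone
per-gene transformations of cohort expression) but makes no fidelity claim to
the original implementation.

## Training and evaluation protocol

All networks train with Adam on MSE (binary cross-entropy for the direct
classifier), learning rate 1e-4, mini-batches of 32 tiles, dropout 0.2,
at most 500 epochs with early stopping — patience 50 epochs without
improvement of the validation metric, best-epoch weights restored. The
regressors' early-stopping metric is the mean per-gene Pearson correlation on
validation tiles (tile level; aggregating to slides every epoch would
multiply the cost for no measurable gain at desk scale). The autoencoder and
classifier stop on validation reconstruction MSE and cross-entropy
respectively.

Evaluation is 5×5 nested cross-validation at the patient level: five outer
folds; per outer training set, five inner train/validation splits each train
one member (autoencoder + tranche regressors), 25 members in total. Held-out
predictions for an outer fold average its five inner members; external
cohorts average all 25. Slides of one patient always stay on one side of
every split. A cheaper k-fold cross-fitting imputer (one member per fold,
internal 20% validation split) is provided for large synthetic cohorts; its
no-leakage guarantee is identical.

For small cohorts, rotation augmentation averages predictions over the four
90° slide symmetries (rotation at the slide level, before tiling). The
direct-supervised comparison model is evaluated by leave-one-out
cross-validation with 30 stratified 80/20 bootstrap splits per held-out
patient (the stratification is this package's choice, to avoid degenerate
single-class training splits at very small n; degenerate draws are redrawn
and logged).

### Numerical choices

- **Input/target standardization.** Compressed tile features consist of a
  large shared component plus small between-tile variation, and log2-CPM
  targets have per-gene means an order of magnitude larger than their
  biological spread. Both the autoencoder inputs and the regressor
  inputs/targets are therefore standardized with training-fold statistics;
  predictions are mapped back to the expression scale, so the scaling is
  invisible to callers and cannot leak across folds. Without it the MSE
  gradient is dominated by the shared offsets and learning stalls.
- **Initialisation.** Seeded uniform fan-in weights (±1/√fan_in); hidden
  biases start at +0.1 so ReLU units are born alive.
- **Determinism.** Every stochastic step (weight init, batch order, dropout
  masks, fold assignment, bootstrap splits, generators) flows from explicit
  integer seeds; identical data + config + seed reproduce identical weights
  on a fixed BLAS.
- **Tranche ties** at equal medians break lexicographically by gene
  identifier; tranches sort descending (highest-expressed genes first).
- **Cox ties** use the Breslow approximation; **Fisher's exact test**
  defaults to the summed-probabilities two-sided convention with
  `alternative="greater"` available; **Woolf CIs** apply the Haldane +0.5
  correction only when a cell is zero (flagged), except in coverage curves,
  where zero-cell thresholds are reported as missing rather than corrected.
- **Average precision** is the non-interpolated step definition with ties
  grouped at one threshold.

## Gene-level evaluation

A gene is *significantly predicted* when the two-sided p-value of the
Pearson correlation between imputed and measured expression across held-out
samples (t-transform, n−2 degrees of freedom) survives Holm–Šídák step-down
correction across all evaluated genes at α = 0.05. The published description of
this criterion does not state sidedness; two-sided is the conservative default
here. Zero-variance genes are reported missing and excluded from the
correction. The enrichment background is the set of genes the model
evaluates, not the genome. Signature scores are mean gene-wise normalized
ranks, hence in [0, 1] and monotone-invariant.

## Expression normalization is a documented stand-in

The upstream publication defers its count normalization to earlier work
without formulas. This package fixes log2(1 + CPM) after an edgeR-style
expressed-gene filter (CPM ≥ 1 in ≥ 20% of samples, re-implemented directly
rather than through an external package) and records the recipe in the
output's `normalization_tag`. TMM or quantile variants would slot in behind
the same interface but are out of scope.

## The feature backend

The production backend in the source work is an ImageNet-pretrained 50-layer
residual CNN producing 2,048 features per tile. Backends here are a
pluggable registry keyed by tag; the built-in default is a *deterministic
texture backend*: per-channel moments, Sobel-gradient histograms, oriented
spectral energy (16 radial × 8 angular FFT bins), and gray-level difference
histograms, variance-stabilised with arcsinh and expanded to 2,048
dimensions by a fixed seeded rectified random projection. The rectification
leaves roughly half of the coordinates always-zero across a cohort,
mirroring the sparsity pattern of pretrained CNN features; the trained
bottleneck representation is strictly denser (tested as an invariant). A CNN
backend can be registered by callers who have one; nothing downstream
depends on the backend beyond the 2,048-width contract and determinism.

The autoencoder's depth, activation and stopping rule are not stated
upstream; this package fixes a single ReLU bottleneck (2048→512→2048),
linear output, dropout 0.2, and the same early-stopping contract as the
regressor, recorded in model provenance tags.

## The synthetic cohort generator

Synthetic cohorts make every stage testable without downloads. Each patient
carries a latent factor vector z (default 3 factors, standard normal clipped
to ±2.5). Slide tiles are procedural textures: a fixed high-contrast carrier
grating guarantees the tissue filter retains tissue tiles, and one
sinusoidal grating per factor (distinct frequency/orientation) has amplitude
12·(1 + 0.35 z_j), so the texture spectrum encodes z approximately linearly;
a blank border ring of background tiles exercises the gradient filter.
Driven-gene log2 expression is β·z mixed with Gaussian noise so that the
variance ratio equals the configured SNR s — the image-predictable
correlation of a driven gene is √(s/(1+s)) by construction (0.894 at the
default s = 4). Null genes are independent noise. Counts are Poisson draws
of the exponentiated log-expression scaled by lognormal library factors, so
the CPM filter and normalization face realistic integer data. GI partners
are drawn from the driven genes *coherently* — the genes whose loadings best
align with a seeded random pathway direction — so the true EMS (computed on
noiseless expression with the same scoring code and persisted in the truth
record) varies widely across patients, as a real pathway-coherent partner
set would. Response labels are Bernoulli(logistic(slope·EMS + intercept)),
default slope 4, intercept −2.

What the generator does **not** emulate: real histology (nuclei, stroma,
stain chemistry), stain batch effects beyond a global tint, spatial
heterogeneity within a slide beyond small amplitude jitter, gene–gene
correlation structure beyond the shared latent factors, and FFPE/FF
preparation differences. Passing tests therefore demonstrate that the
pipeline's machinery is correct and recovers planted image-expression-
response structure at desk scale — not that the texture backend would
extract comparable signal from real slides.

## Desk-scale problem sizes

The package's defaults are the full-scale settings (512-px tiles, 4,096-gene
tranches, lr 1e-4, 500 epochs). The test suite and the acceptance script run
the same code at sizes a single CPU handles in minutes, as a deliberate
design choice: synthetic slides of 512×512 px with 128-px tiles (4 retained
tissue tiles per patient; 128×128 single-tile slides for the larger response
cohorts), 40-patient imputation cohorts with 200 genes in 64-gene tranches,
300-patient response cohorts with 120 genes, and training configs with
learning rate 3e-3 (1e-3 for the autoencoder) and epoch caps of 40–60 (10–12
for the autoencoder). With standardized inputs these converge well within
the caps on the synthetic task; the full-scale defaults remain in place for
real-data use.

## Known limitations and discrepancies

- The printed one-sided proportion test of the aggregate analysis
  (p = 1.28e-6) is not reproducible from the published counts: the standard
  one-sided z-test of the matched-group response proportion (33/69) against
  the cohort rate (1/3) gives p ≈ 0.005. The standard test is implemented;
  the printed value's construction is unknown and deliberately not imitated.
- The aggregate Fisher p printed as 0.002 corresponds to the one-sided
  (OR > 1) test on the reconstructed table; the two-sided convention gives
  0.004. Both are reported.
- One published cohort's statistics (OR 3.2, PPV 53.3%, sensitivity 42.1%,
  ORR 29.7%) are mutually inconsistent under the standard odds-ratio
  definition — no 2×2 table reproduces all four — and are excluded from
  fixtures.
- GI-network *discovery* (inferring SL/SR partners from screens and clinical
  data) is out of scope; networks are inputs.
- Full-scale training on public tumor archives, pretrained CNN weights, and
  the specific clinical cohorts are out of scope; the headline full-scale numbers
  (thousands of significantly predicted genes per cohort, per-cohort
  clinical odds ratios) are not reproducible at desk scale and are not
  claimed by the test suite.
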