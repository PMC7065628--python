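# Methods

## Problem and scope

The pipeline classifies cropped single-cell NAD(P)H autofluorescence
intensity images as *activated* or *quiescent* T cells. The biological
signal: antigen-stimulated T cells enlarge and upregulate metabolism, so
they appear bigger and brighter, with punctate mitochondria-like hotspots.
Because cell morphology and imaging statistics shift between donors, all
evaluation is donor-wise (leave-one-donor-out), and one donor can be held
out of the entire study as a final generalization probe.

The real image set is not publicly deposited, so the package ships a
synthetic generator that reproduces the *statistical structure* the
analysis depends on, and all quantitative claims made by the test suite
are about that synthetic family plus the arithmetic identities of the
published per-donor counts.

## Synthetic cohorts

Each cell is an axis-aligned ellipse (radius ~ Normal, eccentricity
uniform in [0, 0.6]) on a dark background (Gaussian noise σ = 2, clipped
at 0, which keeps the entropy filter meaningful), with a Poisson number
of bright puncta (disk radius 1–3 px, intensity = base × gain, clipped to
255) and a per-pixel mean-lifetime map (Normal, ps) inside the mask.
Class defaults: activated radius 14 px vs quiescent 9 px, base intensity
130 vs 95, puncta count 6 vs 2. `effect_scale` interpolates the activated
parameters toward the quiescent ones; 0 gives a null cohort in which the
two classes are generatively identical.

Donor structure: six donors with class skews (0.13, 0.82, 0.26, 0.24,
0.74, 0.43) — the skew profile of the real study — plus additive
per-donor shifts on radius and intensity means, which reproduce the
cross-donor distribution shifts that defeat the size-only featurization.
Artifact frames (empty, multi-cell, very dim, mean lifetime ≈ 120 ps)
are injected at configurable rates. Defaults use 150 cells/donor, a size
at which every statistical check in the suite is stable while the whole
suite stays desk-fast; study-scale cohorts are a config change.

The generator does **not** model photon statistics, lifetime decays, the
two-photon PSF, cell clumping or segmentation errors beyond the artifact
tags. Passing tests therefore demonstrate that the *pipeline machinery*
is correct and leakage-free and that effect-size recovery behaves
monotonically — not that any accuracy carries over to real microscopy.

## Preprocessing

Fixed cascade order: segment → lifetime filter → entropy/intensity filter
→ pad → augment, with per-donor counts recorded after each stage.

- Segmentation of full scenes is a defined stand-in (Otsu threshold,
  8-connected components, minimum area 20 px); externally produced masks
  (including the generator's ground truth) are accepted directly.
- Lifetime filter: a cell is removed iff its mean lifetime < 200 ps
  (strictly; exactly 200 ps is kept). Cells without lifetime information
  pass unchanged; negative lifetimes are treated as corrupt maps.
- Entropy/intensity filter: Shannon entropy of the 256-bin histogram of
  the full crop (background included) and total intensity; each cutoff is
  mean − kσ of a Gaussian fit over the cohort (k = 2 by default, ≥ 10
  cells required) unless explicit cutoffs are given; a cell is kept iff
  it clears both.
- Padding: crops are centered on an 82 × 82 zero canvas, the odd
  remainder going to the bottom/right. Crops exceeding 82 px in either
  dimension are "extremely large outliers" and are discarded and counted.
- Augmentation: exactly {identity, rot90, rot180, rot270, flip-h,
  flip-v}; augmented copies are training-only by construction of the
  evaluation splits.

## Featurizations

`pixels6724` is the row-major flattened 82 × 82 crop. `scalar2` is (mask
pixel count, total crop intensity). `cp123` is a fixed, documented set of
123 morphology features in the three classic categories: 18 shape/area
(area, perimeter, eccentricity, solidity, extent, axis lengths,
orientation, form factor, bounding-box stats, equivalent diameter, convex
area, Euler number, aspect ratio, compactness, max Feret diameter), 17
intensity-over-mask (mean/median/SD/MAD/min/max/integrated, quantiles,
mass displacement, edge-pixel statistics), and 88 texture values — 11
Haralick co-occurrence statistics (contrast, dissimilarity, homogeneity,
ASM, energy, correlation, entropy, variance, sum average, cluster shade,
cluster prominence) × distances {1, 3} × offsets {0°, 45°, 90°, 135°} on
the mask bounding box quantized to 8 gray levels. The exact feature list
used in the original study is not enumerable from its text, so this set
prioritizes coverage of the same categories and interpretability (area
and intensity dominate) over numeric parity with any external tool;
single-pixel masks produce conventional finite values rather than errors.

## Classifier ladder

All eight models score in [0, 1]; labels are score ≥ 0.5 (the threshold
is a convention — curve metrics are threshold-free). Class imbalance is
handled everywhere by inverse-frequency weights w_c = N / (2 N_c).

1. **Frequency**: constant score = training positive fraction.
2.–4. **Lasso logistic regressions** on the three featurizations
   (scikit-learn saga solver, C = 1/λ, unpenalized intercept). Features
   are standardized internally — the L1 penalty then acts uniformly
   across features of very different magnitudes and the solver is fast
   even on signal-free data — and coefficients are mapped back to the
   original feature scale. Nonzero-coefficient counts and raw/per-SD
   odds ratios are exposed.
5. **MLP**: 6724 → h → 2 with ReLU, weighted cross-entropy.
6. **LeNet-style CNN**: conv5×5(6) → pool → conv5×5(16) → pool → 120 →
   84 → 2 on 82 × 82 single-channel input.
7. **Off-the-shelf transfer**: fully frozen backbone; a new head (global
   average pooling → 1024-unit hidden layer → output) trains on the
   final-layer feature maps.
8. **Partial fine-tuning**: the trailing *n* backbone modules plus the
   output layer train from the backbone's ("pretrained") weights; the
   frozen prefix is evaluated once per dataset through a bottleneck cache
   keyed by (dataset key, boundary) with an input-hash collision check.
   Fitting deep-copies the backbone so the shared pretrained weights are
   never mutated — required for refitting across folds.

The neural models run on a small NumPy engine (dense/conv/pool/ReLU,
float64, minibatch SGD, fixed seeds). Gradients are exact (checked
against central finite differences at 1e-6 relative error in the tests).
Training stops when the loss on a held-aside early-stopping set fails to
improve for 10 consecutive epochs, and the best-epoch weights are
restored (the restore rule is our determinism-friendly choice).

The backbone is pluggable via `BackboneSpec`. An ImageNet-scale
pretrained network (299 × 299 × 3 input, 2048-d features) matches the
interface; the bundled `MiniBackbone` (4 modules of conv3×3/ReLU/pool,
channels 8-16-24-32, 64 × 64 × 3 input, deterministic random
initialization, 32-d pooled features) is the desk-scale instantiation
used by the tests, since the transfer-learning mechanics — freezing,
bottleneck caching, partial unfreezing — are architecture-generic.
Backbone preparation replicates the grayscale crop into three identical
channels and resizes bilinearly.

## Nested cross-validation

For each outer test donor, every hyper-parameter configuration is trained
on each inner fold's training donors (augmented rows) and scored by
average precision on the validation donor's *original* rows; the
configuration with the highest mean AP wins, ties to the earlier-listed.
The final model refits on all inner donors and is evaluated once on the
test donor's original rows. Models needing early stopping sample 25% of
the unaugmented training sources (seeded); those originals form the
early-stopping set and all six copies of each sampled source leave the
training set. With six donors and one holdout this is the 5 × 4 scheme.
Default grids (config-overridable): λ ∈ {0.001, 0.01, 0.1, 1},
hidden units ∈ {64, 256}, learning rate ∈ {1e-2, 1e-3}, batch ∈ {32,
128}, n_finetune ∈ {1..module count}.

Every donor access is appended to an audit log; the holdout test refuses
to run if the holdout donor appears in any earlier training or validation
event. Metrics: confusion counts at 0.5 (ties positive), accuracy,
precision, recall, trapezoidal ROC AUC and step-summed average precision
Σ(R_i − R_{i−1})·P_i (no interpolation); single-class label sets flag the
curve metrics as undefined rather than guessing. The implementation uses
scikit-learn's curve routines and is tested against an exhaustive
brute-force oracle (pairwise-rank AUC, per-threshold AP) on small random
instances.

## Interpretation

- **Temperature scaling**: a single T > 0 minimizes the NLL of
  softmax(logits/T) (bounded scalar minimization on [0.05, 20], xatol
  1e-6 — bounds and optimizer are our choice). T is fitted per test donor
  on the pooled unaugmented validation-donor cells of the outer loop.
  Scaling is strictly monotone in the logit, so rankings and AUC are
  unchanged; on overconfident logits the fitted T > 1 strictly lowers the
  winning-class probability.
- **Embeddings**: UMAP (n_neighbors 15, min_dist 0.1, euclidean) or
  t-SNE (perplexity 30), seeded. Fine-tuned models are embedded per test
  donor (their features differ per fold); static featurizations in one
  joint batch.
- **Saliency**: gradient of the target-class logit with respect to the
  input image, reported on the caller's pixel scale. Guided
  backpropagation additionally zeroes negative upstream gradients at
  every rectifier: backward = upstream · 1[forward input > 0] ·
  1[upstream > 0]. The frequency model is non-differentiable and is
  rejected; the linear models' map is their weight vector.

## Numerical and design choices

- One master seed; per-stage substreams derived by hashing stage names;
  all stochastic components (generation, early-stop sampling, SGD
  shuffling, weight init, embeddings) consume explicit seeds.
- Max-pool gradient ties break to the first maximum in each window.
- Feature CSVs are written with `%.17g` and read with round-trip float
  parsing, so tables survive text serialization bit-exactly.
- Scores tied at the threshold classify as positive.
- Problem sizes in the test suite (25–150 cells/donor, miniature
  backbone, few-epoch CNN fits) are chosen so each statistical assertion
  has comfortable margin at the package's default effect sizes.

## Known limitations

Synthetic realism is deliberately minimal (no photon noise, no
segmentation errors, no label noise). The 123-feature set is not
numerically comparable to CellProfiler's. The miniature backbone carries
no pretrained visual knowledge, so absolute transfer-learning accuracies
on synthetic data say nothing about ImageNet-scale transfer; only the
mechanics are validated. Statistical comparison *between* models is out
of scope: each model is tuned and evaluated once per donor.
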