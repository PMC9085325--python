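# Methods

## Model

`imgram` classifies 2-D grayscale images by converting them to text and
applying n-gram text-categorization machinery. The modelling assumptions
are:

- **Intensity quantization is lossy but sufficient.** Gray values are
  binned into 16 equal 16-level bins (`A`–`P`). This caps the vocabulary
  at 16 + 16² + 16³ = 4368 tokens for orders {1, 2, 3} and discards
  within-bin contrast (reconstruction error ≤ ±8 gray levels per pixel).
  Inputs must be integer-valued; non-integer images are rejected rather
  than rounded, since the bin edges are defined on integers.
- **Texture is read horizontally.** Tokens are contiguous windows along
  rows only — no vertical or 2-D windows, no wrap across rows. The
  method is therefore orientation-sensitive, which is why the optional
  preprocessing can rotate a region's longest diameter to horizontal
  first.
- **Documents are bags.** Token position within the image is discarded;
  only per-image counts matter. All orders are pooled into one bag for
  the TF denominator (a per-order normalization is available via
  `tf_per_order` for users who want each order to be its own bag).
- **The feature space is fixed by the training split.** Test-time tokens
  never seen in training are dropped. Inside cross-validation the
  vocabulary, the TF-RF statistics, the rank-sum p-values, the ECE
  ranking, the retained set and the feature scaler are all refit per
  fold from the training split only.

## Parameters

| parameter | default | units / range | rationale |
|---|---|---|---|
| `orders` | {1, 2, 3} | n-gram lengths | storage and complexity grow exponentially in n; 1–3 is the standard working range |
| `weighting` | `tf` | {tf, tf_rf} | TF-RF adds supervised, imbalance-aware emphasis: factor log₂(2 + (N/P)·a/max(1, c)), ≥ 1, = 1 when a = 0 |
| `alpha` | 0.05 | significance level | raw per-feature filter; Benjamini–Hochberg available (`correction="bh"`) but off by default |
| `fraction` | 1.0 | (0, 1] of valid features | floor-with-minimum-one retention; 0.25 typically costs almost nothing in AUC |
| `svm_c`, `svm_gamma` | 10, 0.01 | RBF-SVM | the reference operating point; C and γ are the canonical RBF parameterization |
| `mlp_hidden` | (3, 6, 3) | layer sizes | three small hidden layers; ≤ 100 epochs, learning rate 0.01 |
| `goal` | 1e-5 | loss tolerance | mapped to the network's loss-improvement stopping tolerance (scikit-learn `tol`); an absolute loss target is not exposed by the backend |
| `n_folds` | 10 | stratified folds | stratification keeps per-class fractions meaningful at small n |
| `scale` | on | — | selected columns are standardized with train-fold mean/sd; RBF-SVM behaviour depends on scale |
| diffusion | κ = 30, dt = 0.2, 10 iters | gray levels / step | standard Perona–Malik practice with exponential conductance; dt ≤ 0.25 for stability of the explicit 4-neighbour scheme |
| `white_threshold` | 250 | gray level | border-fill brightness cutoff |

## Statistical choices

- **Rank-sum filter.** Two-sided Wilcoxon rank-sum (Mann–Whitney) per
  feature column on the *weighted* feature values, normal approximation
  with tie and continuity correction. The continuity correction is kept
  because it markedly improves accept/reject agreement with the exact
  permutation distribution at small group sizes (e.g. n = m = 4, U = 1:
  exact p = 0.057; with continuity 0.061, without 0.043 — the latter
  flips the decision at α = 0.05). A column constant across both groups
  gets p = 1 and is never selected. The filter runs on weighted values,
  so the valid-feature pool is weighting-mode-dependent by design.
- **ECE ranking.** p(t) and the class posterior use document *presence*
  (count > 0), not TF magnitudes. ECE is p(t) times a KL divergence, so
  it is nonnegative, zero for features present in every document of
  every class, and zero for absent features. Ties are broken by
  vocabulary order (token length, then lexicographic), making the
  retained set deterministic.
- **AUC.** Computed by the rank (Mann–Whitney) formulation with average
  ranks, so tied scores contribute 1/2. ROC/AUC is pooled over the
  concatenated test-fold scores.
- **Ternary protocol.** Three pairwise subclassifiers over the class
  pairs (1,2), (1,3), (2,3), each fitting its own vocabulary, weighting
  (positive class = the pair's first class), selection and scaler.
  Majority vote; the rare 1-1-1 tie goes to the subclassifier with the
  largest absolute decision score.

## Synthetic data: what it emulates, and what it does not

The generator plants class-discriminative *horizontal* gray-level motifs
(runs of 2–3 quantization bins) into i.i.d. uniform background noise
drawn from a shared set of background bins. Defaults: 32×32 images,
background bins {0..7}, motifs (10, 11, 12) vs (13, 14, 15) (plus
(8, 9, 8) for the third class), one expected motif per row
(Poisson-distributed counts, uniform non-wrapping start columns). These
choices are deliberate:

- shared background bins make the null token distribution exchangeable
  across classes, so the rank-sum filter's type-I rate is honestly
  calibrated (~5 % at α = 0.05 over ~584 features);
- bin-disjoint motifs give known, disjoint truth tokens whose recovery
  in the top-25 % ECE ranking can be asserted exactly;
- 32×32 keeps a single image at ~2900 tokens and full 10-fold
  experiments in seconds.

What the generator does **not** emulate: ultrasound speckle physics, OCT
layer anatomy, intensity gradients, correlated noise, or annotation
noise. Passing tests demonstrate that the pipeline recovers planted
row-wise texture under exchangeable noise and that its statistics are
calibrated — not that clinical-grade accuracy transfers to real scans.
The synthetic tasks are separable by construction, so AUC ≈ 1 is the
expected outcome, and the fraction-robustness check (|AUC(100 %) −
AUC(25 %)| ≤ 0.05) is a consistency property, not a clinical claim.

## Numerical and degenerate-input handling

- Zero-token documents get an all-zero TF row (no 0/0).
- A token absent from all training documents has a = c = 0, giving an
  RF/TF-RF factor of exactly log₂ 2 = 1.
- `select_top_fraction` retains max(1, ⌊fraction · n_valid⌋) features;
  if nothing passes the filter it returns an empty selection with a
  warning, and the pipeline refuses to train on it.
- Diffusion is an explicit scheme with reflecting borders: it conserves
  total intensity up to final rounding and obeys a min/max principle
  (output range within input range) for dt ≤ 0.25.
- Rotation measures the orientation of the farthest pair of mask points
  (via the convex hull when available, all points for degenerate masks),
  rotates about the array centre with `reshape=True` (equivalent to the
  centroid convention up to translation), bilinear for the image and
  nearest-neighbour for the mask, and refines the angle with a small
  grid search that minimizes the measured residual of the rotated mask —
  pixel discretization of thin masks would otherwise leave a few degrees
  of bias. Masks so small that 2° is below the pixel-grid resolution
  (e.g. a ~15-pixel diagonal) cannot be aligned more precisely by any
  method.
- All randomness (fold shuffling, per-fold network initialization,
  synthetic images) derives from one top-level seed via deterministic
  seed splitting; identical seeds give byte-identical CV reports.

## Problem sizes

Tests and the acceptance script use 50 images per class (binary) and 15
per class (ternary) at 32×32 — enough for ~590-token vocabularies,
stable fold statistics and a clearly separable planted signal, while a
full run of the suite plus the acceptance script completes in well under
a minute.

## Known limitations

- Horizontal-only tokenization ignores vertical texture entirely.
- The raw (uncorrected) α = 0.05 filter admits ~5 % of null features;
  this is intentional (the downstream ECE ranking and classifier tolerate
  them) but means "valid feature" is not a discovery claim.
- The BP network's `goal` (absolute loss target) is approximated by a
  loss-improvement tolerance.
- No automatic region segmentation is provided; ROI masks, when used,
  must be supplied externally.
- PipelineConfig is consumed directly by library calls and the CLI; a
  YAML file with the same field names is accepted by `imgram run
  --config`.
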