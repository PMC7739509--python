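# Methods

This note documents the models and numerical choices behind `sheartex`,
the assumptions they rest on, and what the synthetic evaluation does and
does not demonstrate.

## Shearlet system

The decomposition is a band-limited, cone-adapted directional filter bank
constructed directly on the discrete frequency grid of the target image
shape. Two window families define it:

* **Radial (scale) windows.** With the log-radial coordinate
  l = log₂(2r) (r in cycles/sample, so l = 0 at the Nyquist ring), smooth
  Meyer-type steps G_s rise over one octave each. The squared windows
  telescope: lowpass² = 1 − G₁, band_s² = G_s − G_{s+1}, and the finest
  band saturates at 1 beyond Nyquist so the square-grid corners are
  covered. By construction ∑ band² + lowpass² = 1 exactly.
* **Angular (direction) windows.** Raised-cosine wedges of width 2π/K in
  orientation (period π), centred at −45° + (k − ½)·180°/K, so directions
  k = 1..K/2 tile the horizontal-frequency cone and k = K/2+1..K the
  vertical cone. Adjacent wedges overlap with cos²+sin² = 1, giving an
  exact angular partition of unity.

The product windows therefore form a Parseval-type frame: forward
transform = inverse FFT of (spectrum × window), inverse transform = sum of
(subband spectra × windows), with reconstruction error at machine
precision (≈ 1e−15, asserted < 1e−6 in tests). This construction differs
from shear-matrix-based systems in how wedges are parameterised but has
the same multi-scale directional tiling; the package's contracts
(frame property, orientation selectivity, subband count S·K) are tested
directly rather than assumed from the construction.

**Complex coefficients.** Each directional filter is restricted to the
half-plane containing its orientation vector (weight ½ on the boundary),
the 2-D analogue of the analytic signal. The real part of the complex
coefficient equals the symmetric-filter subband, so reconstruction uses
real parts only. On even-sized grids the Nyquist row/column alias ±½
cycles/sample; the angular windows are symmetrised, and the half-plane
sign antisymmetrised, under the grid's frequency-negation map so the
Hermitian pairing — and hence exact reconstruction — survives
discretisation.

**Shapes.** The system builds at the image's own (rows, cols); nothing
requires square support, so rectangular images are decomposed without
padding. Both dimensions must be ≥ max(32, 2^(S+1)) so the coarsest band
is resolvable. Defaults S = 4, K = 8 (32 directional subbands), subbands
ordered scales coarse→fine, directions ascending; every concatenated
feature vector depends on this ordering, so it is fixed.

## Relative phase

RP is the wrapped difference between a coefficient's phase and its
neighbour along the cone's shear direction: next column for k ≤ K/2, next
row for k > K/2. Raw differences lie in (−2π, 2π) and are wrapped by
d − 2π·round(d/2π), mapping −π to π so RP ∈ (−π, π]. The neighbour of the
last column/row is taken circularly, keeping the full subband shape so
all per-subband descriptors see identically sized inputs; edge-trimming
would be a one-line change. RP is invariant to a global phase shift
(differences only), which tests assert.

## Descriptor families

All families are deterministic; identical input gives bit-identical
output.

* **Co-occurrence (cm).** Subbands are min–max rescaled and uniformly
  quantized to Ng = 8 levels (constant subbands map to level 1). Four
  GLCMs at offset distance 1 and orientations 0°/45°/90°/135° are
  symmetrized, normalized, averaged and renormalized; 8 levels keep the
  four matrices well-populated on 100–200 px subbands and Ng is exposed
  as configuration. Twenty statistics are computed with natural
  logarithms and zero-variance guards (correlation and the information
  measure return 0 for degenerate matrices, so outputs are always
  finite). Two deliberately distinct entries honour the 20-item list:
  `sum_of_squares` is taken about the mean of the matrix *entries* (the
  convention of the widely circulated MATLAB GLCM feature script this
  literature builds on), while `variance` is the marginal level variance.
  A brute-force double-sum oracle checks all 20 statistics to 1e−10.
* **LBP (riu2).** P = 8 neighbours at radius R = 2, bilinear
  interpolation, sign rule s(x) = 1 iff x ≥ 0, rotation-invariant uniform
  labels, i.e. P + 2 = 10 histogram bins normalized to sum 1. The
  histogram is accumulated over interior pixels only (border of ⌈R⌉
  discarded) to avoid inventing padding values.
* **LOSIB.** Mean absolute difference between each centre and its p-th
  neighbour; at R = 1, P = 8 the neighbours are exactly the 8-connected
  integer offsets (no interpolation), enumerated counter-clockwise from
  East. Interior pixels only. Scales linearly with the input, unlike cm
  and lbp which are invariant to positive rescaling — tests pin all three
  behaviours.
* **SFTA.** Subbands are min–max rescaled to 256 integer levels (multi-
  level Otsu needs a discrete histogram; it also makes the 21-vector
  invariant to affine rescaling of the coefficients, and the region mean
  gray level is computed on the same 0–255 scale). Thresholds come from
  an exact dynamic-programming multi-level Otsu (O(n_t·bins²), ~1 ms per
  subband) that maximizes between-class variance; tests verify it attains
  at least the objective of `skimage.filters.threshold_multiotsu`, which
  at 5 classes is several orders of magnitude slower per call. The binary
  set is fixed to 2n_t − 1 images — the n_t upper sets {x > t_i} plus the
  n_t − 1 consecutive band-pass sets {t_i < x ≤ t_{i+1}} — matching the
  published 21 = 3·(2·4 − 1) attributes per subband. Each binary image is
  summarised by (a) the box-counting dimension of its border (set pixels
  with an unset 4-neighbour, image boundary counting as unset), using
  dyadic box sizes from 1 to half the minimum dimension and the
  least-squares slope of log count vs log(1/size); (b) mean gray level
  over the region; (c) pixel count. Constant subbands fall back to
  all-zero binaries (feature triple (0, 0, 0)) rather than failing.
* **CM-dot (cmdot).** The published description — "inner product of the
  co-occurrence matrix and magnitude coefficients" — underdetermines the
  construction, and no stated parameter reproduces its original feature
  count. The package fixes a deterministic stand-in: the Ng × Ng
  block-mean reduction of the magnitude subband is Hadamard-multiplied
  with the subband's mean GLCM and summarised by column-wise maxima
  (length Ng = 8 per subband). The contract is fixed length and
  determinism; the construction is flagged as reverse-engineered and the
  `meshkini` baseline shares it.

## Fusion and reduction

Fusion is pure concatenation in a fixed order — RP blocks before
magnitude blocks, families in (cm, lbp, losib, sfta, cmdot) order — so
under S = 4, K = 8 Fusion #1 has 3776 columns and Fusion #2 has 1792.
Standardization precedes PCA (mixed-scale descriptors make unstandardized
PCA meaningless); zero-variance training columns are dropped with a
logged count, detected by exact value range so constant columns with
floating-point cancellation noise are still removed.

PCA is fitted per training fold — never globally — so no test statistics
leak into preprocessing; a corruption test asserts fitted parameters are
bit-identical when test rows change. A global-fit variant would be easy
to add but is deliberately not the default. The leading loadings are
rotated to maximize the orthomax criterion with γ = 1 (varimax), max 1000
iterations, tolerance 1e−6; the rotation is orthogonal, so the projected
subspace, and with a full basis all pairwise distances (to 1e−8), are
preserved. Each basis column's largest-magnitude loading is made positive
for run-to-run determinism. The component sweep evaluates cross-validated
accuracy at 50-component increments plus the maximum usable count
min(n_features, n_train − 1).

## Classification and evaluation

* **SVM**: RBF kernel, C = 5, kernel width 1/n_features on standardized
  inputs, one-versus-one multiclass decisions via the libsvm SMO-style
  dual solver; one-vs-rest decision values serve as ROC scores.
* **DTB**: 100 bootstrap-resampled decision trees with √n_features
  candidate attributes per split, seeded for bit-reproducibility; class
  vote fractions serve as scores.
* **Cross-validation**: stratified k-fold (default; keeps minority
  classes in every fold) with deterministic seed-driven assignment; if
  the smallest class has fewer than k members the plan falls back to
  unstratified folds with a warning. Metrics are ACC, AUC, sensitivity
  and precision; multiclass values are macro-averaged one-vs-rest, binary
  problems take a configurable positive class. Aggregates are per-fold
  mean ± std plus a pooled confusion matrix.

## Synthetic data: what it shows and what it does not

Each class is an oriented sinusoidal grating (wave-vector angles evenly
spaced over [0°, 180°)) plus i.i.d. Gaussian noise, min–max rescaled to
[0, 1]. Defaults: 4 classes × 50 images, 128 px, 24 cycles per image
(normalized frequency 0.1875, inside the finer scale bands), contrast 1,
noise sd 0.3 — i.e. noise ≈ 0.6× the grating amplitude, enough that raw
pixels are visibly corrupted while orientation energy remains
recoverable. Per-image seeds derive from the master seed via
`SeedSequence(seed, spawn_key=(class, index))`, so datasets are
bit-reproducible and extending them never reshuffles existing images.

Gratings were chosen over, say, Gaussian random fields because class
identity is carried *exactly* by orientation — the property shearlet
subbands index — making end-to-end recovery tests sharp: a nearest-
centroid rule on cm+losib features must reach ≥ 0.9 accuracy, and the
full Fusion #1 + SVM pipeline ≥ 0.95 under 10-fold CV. What passing does
**not** show: robustness to stain variation, magnification mixtures,
class imbalance, or textures whose discriminating statistics are not
orientation-frequency energy — all properties of real histology corpora.
Real-data performance must be established on real data via the folder
loader; the synthetic results validate the machinery, not the biology.

## Problem sizes

Default test and acceptance runs use 64–128 px images, 200-image
datasets, 10-fold CV and the 50-step component sweep; extraction runs at
roughly 0.8 s per 128 px image on one core, dominated by SFTA and LBP.
These sizes were chosen so the complete validation cycle runs comfortably
on a laptop core while still exercising every stage at the published
dimensionalities.

## Known limitations

* The cmdot construction is a documented stand-in (see above); its
  feature count differs from the original publication's, so totals that
  depend on it are not comparable.
* The box-counting dimension on 128 px subbands is a coarse estimator
  (±0.15 tolerance on analytic curves); it is a feature, not a
  measurement of fractal geometry.
* SVM AUC uses uncalibrated decision values; calibrated probabilities
  would change AUC slightly but not the ranking-based comparisons.
* `circvar`-based baseline statistics follow the 1 − R (resultant
  length) convention.
* No imbalance handling (SMOTE-style resampling) and no patient-grouped
  splitting are applied by default; the fold planner accepts precomputed
  assignments if grouping is needed.
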