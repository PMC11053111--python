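# Methods

This note documents the modelling assumptions, parameter choices and
numerical conventions of `polarmace`, and what the synthetic-data
generator does and does not emulate.

## Polar-map representation

The analysis representation is the tabular 16×36 measurement matrix, not a
rendered polar-map image: row `m` indexes radius (row 1 innermost/apex,
row 16 basal), column `n` angle at 10° per column, columns 1 and 36
adjacent. Raw 24×36 exports carry 8 extra outer rows that fall outside the
standard display and are discarded on load; loading a 16-row file and a
24-row extension of it yields identical matrices. All entries must be
finite and nonnegative — violations are hard errors, never imputed.

**17-segment parcellation.** The AHA parcellation is realised as four
concentric rings of configurable depth (default 4/4/4/4 rows from the pole
outward): apex = segment 17 (all columns of the innermost ring), apical
ring = 4 blocks of 9 columns (segments 13–16), mid and basal rings = 6
blocks of 6 columns each (segments 7–12, 1–6). Blocks start at a
configurable angular offset and wrap periodically. The exact row/ring
correspondence and angular origin of the upstream quantification software
are not recoverable, so both are parameters; no model depends on the
anatomical wall labels. Default pixel counts: 144 for the apex, 36 per
apical segment, 24 per mid/basal segment (total 576).

## Signals

- Rest flow is normalised to a reference rate-pressure product of
  8500 mmHg/min before the reserve is formed; stress flow is never
  adjusted. The adjustment is a flag on MFR/MFC derivation, default on.
- MFR is the pixelwise stress/rest ratio. A nonpositive rest pixel is a
  domain error naming the pixel — silent clamping would corrupt every
  downstream feature. The synthetic generator enforces a positive rest
  floor (0.05 mL/min/g) so this cannot occur in generated data.
- The MFC radius is the pixelwise Euclidean norm of (sMBF, MFR). It is
  bounded below by max(sMBF, MFR) and above by their sum; both bounds and
  the monotonicity of MFR/MFC in stress flow are property-tested.

## Feature extraction

**First-order (18) and texture (75) features** follow the IBSI-compatible
definitions used by standard radiomics toolkits, computed in 2D over the
full matrix (no regional masks, no shape or filtered-image features).
Conventions that matter for reproducibility:

- Discretization: fixed bin width = (pooled cohort max − min)/16, bins
  anchored at the pooled minimum. The pooled range follows the stated
  whole-data rule and is therefore split-independent; a strict mode
  recomputes it from the training rows of each split only (values below
  the training minimum collapse into the first bin).
- Moments are population moments; kurtosis is the raw (Pearson) form, not
  excess; skewness/kurtosis of a constant image are defined as 0.
- Texture families: GLCM (24 features; distance 1, four 2D directions,
  symmetric matrices, per-angle feature values averaged), GLRLM (16; four
  directions averaged), GLSZM (16; 8-connected zones), NGTDM (5;
  8-neighbourhood means, edge pixels use available neighbours), GLDM (14;
  dependence = centre + 8-neighbours equal after discretization, α = 0).
  Gray-level weights use the actual discretized values present in the
  image; log terms add machine epsilon.
- The matrix is treated as a *flat* image for texture: the periodic
  column adjacency is deliberately ignored, matching default texture
  toolkits. This is a known, documented distortion at the 1/36 seam.
- Feature order is fixed and alphabetical within family, so per-split
  selection counts are comparable across runs.
- Conformance is tested two ways: against an independent pure-loop
  implementation of every definition (10⁻⁶ relative tolerance on random
  fixtures), and against scikit-image's co-occurrence code for the GLCM
  family.

**Standardization** uses training means and population SDs; constant
training columns transform to 0 so penalized models ignore them. In the
pipeline the standardizer is fitted on the *oversampled* training set
(oversampling precedes training in the protocol); a strict
pre-oversampling option exists.

**Clinical covariates** (19 by default) pass numerics through and one-hot
encode categoricals against a declared schema; an unseen level at
transform time is an error naming variable and level.

## Models

**ElasticNet logistic regression / Cox PH.** Only the mixing parameter
l1_ratio is tuned, over the fixed grid {0.50, 0.85, 0.9, 0.92, 0.95, 0.97,
0.98, 0.99, 0.995, 0.999, 1.0}, by stratified 5-fold CV on the training
set (AUC for classification, Harrell's C for survival); ties break toward
the sparser (larger) value; the model is refit on the full training set at
the winner. The overall penalty strength is a second, deliberately fixed
hyperparameter (logistic: inverse strength C = 1; Cox: α = 0.05),
configurable but not searched — the grid is one-dimensional by design.
Stratified CV folds guarantee both classes (and events) per fold.
Selected features are those with |coefficient| > 10⁻¹⁰.

**CNNs.** Two small architectures over the raw 16×36 matrix (no input
scaling):

- CNN 1: conv(64 filters 5×5, ReLU) → global average pooling →
  dense(256, ReLU) → dense(2, softmax); 18 818 parameters, independent of
  convolution padding.
- CNN 2: conv(64, 5×5, ReLU) → 2×2 max-pool → conv(128, 3×3, ReLU) →
  2×2 max-pool → flatten → dense(256, ReLU) → dense(2, softmax); 535 042
  parameters with unpadded convolutions (padding would change the flatten
  width, so "valid" is the architecture-defining choice).

Training: Adam (learning rate 10⁻³, batch 32 — conventional defaults,
configurable), categorical cross-entropy, combined L1+L2 penalty on the
kernels (10⁻⁵ each), 50 epochs by default. The implementation is a
self-contained NumPy conv-net (im2col convolutions, explicit backprop);
at this input size it trains in seconds per epoch and is bit-reproducible
from the spec seed (Glorot-uniform init and batch shuffling both seeded).
Max-pool gradients are split equally among tied maxima.

**Augmentation** (CNN families only, training partitions only): the set is
exactly quadrupled — originals, right column shift, left column shift
(cyclic, ±10°), and the radial stretch (erase the 3 outer rows,
re-interpolate rows 1–13 onto 16 rows linearly, endpoints to endpoints, so
constant and linear radial profiles are preserved). Augmentation is
applied after oversampling, so triplicated positives are augmented too.
The shifts are pixel permutations and leave every first-order statistic
invariant — a property test, and the reason augmentation is pointless for
the intensity-feature families.

**Late fusion** averages image and clinical probabilities trained on the
identical split. Cox linear predictors are unbounded, so the survival
variant z-scores each stream with its own training cases before averaging
— an interpretation, flagged as such.

## Validation protocol

100 stratified 75/25 splits (repeat r uses seed r, shared across all
model families so comparisons are paired); per-class training counts are
floor(0.75 · class size) — 175 = 35 + 140 for 234/47 cohorts. Positives
are triplicated in the training set (245 = 105 + 140) and the order
reshuffled with the split seed. Metrics:

- AUC by the midrank convention (equals the normalized rank-sum
  statistic; cross-checked against the pairwise-ordering oracle and
  scikit-learn).
- Youden cutoff: maximizes sensitivity + specificity − 1 over observed
  scores (case positive when score ≥ cutoff); ties break toward higher
  specificity, then the larger cutoff. The cutoff is found on the
  test-set scores of each split by default (a train-derived option
  exists); reported sensitivity/specificity are averages of per-split
  values.
- Harrell's C over comparable pairs (earlier time must be an event; risk
  ties count ½); cross-checked against lifelines.
- Bootstrap: 95% percentile CIs of the mean from 1000 resamples of the
  per-split metrics, with an independent fixed bootstrap seed; pairwise
  comparisons use the paired bootstrap of per-split differences,
  two-sided p floored at 1/1000.
- Risk groups: median score split (ties to the low-risk group),
  Kaplan–Meier estimates and the standard two-group log-rank test via
  lifelines.

No-leakage is enforced structurally (standardizers, bin rules in strict
mode, cutoff search and model fits only ever see training rows) and
audited in tests across every repeat.

## Synthetic cohort generator

The generator emulates the marginal statistics of a suspected-ischemia
[82Rb]-PET cohort; defaults are calibrated once to published cohort-level
medians and left alone:

- 234 patients, target event rate 0.20 (intercept auto-calibrated by
  bisection on the simulated cohort, giving 47 events at the default
  size).
- Rest flow: lognormal, median 0.82 mL/min/g (log-sd 0.36 from the
  reported interquartile range), times a smoothed multiplicative noise
  field (white Gaussian, sd fraction 0.08, 3×3 moving average with
  periodic columns and clamped rows), floored at 0.05.
- Stress flow: rest × lognormal healthy multiplier (median 2.4, log-sd
  0.30), so the global sMBF median lands near 1.96 mL/min/g and the
  RPP-adjusted MFR in the 2.4–2.9 range.
- Defects: with probability 0.5, 1–2 contiguous angular wedges (half-width
  2–6 columns with periodic wrap) growing inward from the basal edge
  (depth 4–12 rows), multiplying stress flow by a severity in (0.3, 0.8).
  Defect centres anchor on three coronary-territory positions (columns 6,
  18, 30 ± 3 columns of jitter) rather than uniformly at random — focal
  disease is territorial, and this is what gives regional models their
  advantage over the global mean.
- Hemodynamics: rest HR ~ N(70, 10), SBP ~ N(136, 23), so the
  rate-pressure product spans the 8500 mmHg/min reference.
- Outcomes: event ~ Bernoulli(sigmoid(η)) with
  η = β₀ + β_g·(global sMBF) + β_d·(defect burden) + β_c·(clinical score);
  defaults β_g = −1.2, β_d = 15, β_c = 0.5. Event times are exponential
  with a rate increasing in the cohort-centred η (slope 0.5, scale 700
  days); censoring is uniform on 400–900 days (median follow-up ≈ 650
  days); the observed time is the minimum. Defect burden is the masked
  pixel fraction weighted by (1 − severity).
- Clinical rows: 19 variables — age and BMI (normal, medians ≈ 72 y and
  31 kg/m²), 14 named binary covariates at published prevalences
  (hypertension 0.73, smoker 0.45, dyslipidemia 0.68, diabetes 0.36, ...)
  and 3 neutral placeholders standing in for covariates whose identity is
  not public. Known CAD, diuretics and history of MI are tilted by the
  latent clinical risk score so their prevalence differs between event
  groups.

Ground truth (defect masks, severities, linear predictor, event
probability) is stored with every cohort for recovery tests.

**Fidelity limits.** Calibration is to *global marginal* medians only; no
per-segment flow distributions, no attenuation/reconstruction physics, no
kinetic modelling, and covariates are conditionally independent given one
latent score. A model that passes the recovery tests here demonstrably
extracts planted focal and global-flow effects through the full pipeline;
that is evidence about the pipeline's correctness, not about clinical
performance on real data, which cannot be reproduced without the private
cohort.

## Test and acceptance sizing

The repeated-split recovery tests run at 20 repeats (5 for the CNN smoke
test, 10 epochs, 120 patients), sizes chosen so the full suite and the
acceptance script each complete in minutes on a single CPU while keeping
the planted-effect assertions comfortably powered. The acceptance script
reseeds everything from its `--seed` argument; the test suite uses fixed
seeds throughout.

## Known limitations

- The flat-grid texture convention ignores the polar seam (above).
- The Cox late-fusion z-scoring is one reasonable reading of
  probability-averaging for models that emit no probabilities.
- The pooled discretization range technically sees test-set values; the
  strict mode exists precisely to quantify that (small) leak.
- CNN training, while exactly reproducible, is NumPy-based and therefore
  slower than GPU frameworks at larger input sizes than used here.
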