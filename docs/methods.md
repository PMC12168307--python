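# Methods

`nephroradiomics` reimplements a renal-MRI radiomics analysis for
discriminating the two Beckwith-Wiedemann syndrome (BWS) genotype groups
that differ in renal predisposition: UPD+IC1 (paternal uniparental disomy
of 11p15 pooled with IC1 gain of imprinting) versus IC2 (loss of
imprinting at imprinting control region 2). Because no patient data are
deposited, the package ships a synthetic-cohort generator that reproduces
the statistical structure the analysis depends on, so every downstream
stage is testable end to end.

## Synthetic cohort

Each subject consists of paired T2-weighted (T2WI) and apparent diffusion
coefficient (ADC) volumes plus left/right kidney parenchyma masks.

**Geometry.** Kidneys are axis-aligned superellipsoids
(|x/a|^p + |y/b|^p + |z/c|^p <= 1, p = 2.5) with the long axis along the
slice direction, semi-axis ratios 1 : 0.42 : 0.34 with +-8% jitter, and a
concentric cavity (axes scaled by 0.35) excluded from the mask to emulate
the renal collecting system — masks are parenchyma-only by construction.
Semi-axes are solved analytically from the target parenchymal volume via
the closed-form superellipsoid volume 8abc Γ(1+1/p)³/Γ(1+3/p), so the
rasterized voxel volume matches the drawn volume up to surface-voxel
quantization. The default grid is 96x96x36 voxels at 0.9375x0.9375x5 mm
(240 mm field of view on a 256 matrix; the 5 mm slice pitch counts the
4 mm slice plus 1 mm gap). A 64x64x28 grid at 1.40625 mm in-plane
(`coarse_grid()`) is used for fast runs; it changes rasterization
granularity only, not the planted statistics.

**Volume model.** Total renal volume (cm^3) is linear in age with Gaussian
noise, per class:

| class   | intercept | slope (cm^3/month) | noise SD |
|---------|-----------|--------------------|----------|
| UPD+IC1 | 90.4      | 0.949              | 28.3     |
| IC2     | 58.6      | 1.20               | 14.8     |

With integer ages uniform on [6, 48] months (SD 12.4), these give
population medians ~116 and ~91 cm^3 at the mean age and age-volume
Pearson correlations r = slope*SD_age/SD_vol of 0.385 and 0.715 — the
cohort quantities the analysis contrasts. The noise draw is truncated at
+-2.33 SD so extreme draws always fit the grid; the truncation changes the
implied r by < 0.01. The left-kidney fraction is N(0.5, 0.02) clipped to
[0.45, 0.55].

**Texture.** Parenchymal texture is a Gaussian random field (white noise
smoothed by a Gaussian of the class's correlation length, normalized to
unit variance) scaled by an amplitude: correlation length 6 mm (UPD+IC1)
vs 3 mm (IC2) at amplitude 60 on T2WI and 80 on ADC. Correlation length is
the heterogeneity dial: Busyness and related neighborhood statistics rise
monotonically as it shrinks (property-tested, Spearman rho > 0.8).

**Lesions, ADC, clinical flags.** Cyst-like inclusions (hyperintense on
both sequences at 10 texture-SD above base, radius 3-6 mm) occur per
subject with class rates 0.375 vs 0.08, mirroring the nonmalignant renal
anomaly incidences. Subject-level mean ADC is N(1340.13, 67.53) vs
N(1343.81, 75.81) on the 1e-6 mm^2/s scale (the conventional 1e-3 scale
is internally inconsistent with the magnitude the cohort tables print;
the 1e-6 scale matches those numbers). Seven binary phenotype flags are
independent Bernoulli draws at the class incidences of the clinical table
(e.g. omphalocele/umbilical hernia 9/24 vs 17/25).

**Seeding.** One master seed determines everything. Per-subject phantom
seeds are SHA-256 hashes of (master_seed, subject_index) reduced below
2^31; clinical covariates use numpy substreams seeded by
(master_seed, 1, subject_index). Identical specs reproduce byte-identical
cohorts within this implementation.

**What the phantoms do not emulate:** anatomical kidney shape, MR physics
(no k-space, bias field, or partial-volume model), inter-kidney
asymmetry pathology, and spatially structured clinical-flag dependence.
Passing tests therefore demonstrate the pipeline's statistical machinery,
not clinical performance on real images.

## Volumetry

Per-kidney volume is (voxel count) x (spacing product) on the native grid;
total volume is exactly left + right. Mean T2WI and ADC are taken over the
mask union on raw images. Totals are classified against a packaged
normative table of total renal volume (mean +- 2 SD) for normal children
aged 6-48 months in half-year bands; classification uses strict
inequalities ("above" means strictly exceeding mean + 2 SD), and band
membership is half-open [lo, lo+6) with exactly 48 months out of range.
Age-volume association per class is the Pearson correlation with the
two-sided t-transform p-value.

## Derived-image bank (15 types)

original; Laplacian-of-Gaussian at sigma 1 mm and 2 mm (sigma converted to
voxels through the spacing, response multiplied by sigma^2 for
cross-scale comparability, and the truncated kernel's DC gain subtracted
so constants map exactly to zero); the 8 subbands (LLL...HHH) of a
single-level stationary coiflet-1 decomposition (normalized so subband
energies sum to the input energy and the input is recoverable to 1e-5);
and four noise/smoothing types — shot noise (Poisson(I/scale)*scale,
seeded), binomial blur ([1,2,1]/4 separable kernel, 4 passes), speckle
noise (multiplicative Gaussian, sigma 0.1), and additive Gaussian noise
(sigma 0.1 of the image SD). The identity of the four types beyond
LoG/wavelet/shot/binomial is a modelling choice: the source analysis names
only examples of its 15 filters. All convolutions use reflect boundaries;
noise types are pure functions of (volume, seed, params).

## Feature bank (1246 columns)

16 voxel-based shape features on the original-geometry mask, plus 82
intensity features (18 first-order + 64 texture) per image type x 15
types. Texture families and counts: GLCM 20, GLRLM 14, GLSZM 14, GLDM 11,
NGTDM 5. The manifest ships as a versioned JSON data file; names follow
`<imagetype>_<family>_<feature>`.

Conventions that differ across published tools, fixed here:

- Discretization: fixed bin count 32 over the masked range per image type
  (well-defined for signed filtered images); min maps to level 1, max to
  level Ng.
- GLCM: 13 unique directions at Chebyshev distance 1, symmetrized, pooled
  over directions, normalized to sum 1.
- GLRLM: runs along the 13 directions, summed; RunPercentage divides by
  Np x 13.
- GLSZM: zones are 26-connected equal-level components.
- GLDM: alpha = 0, 26-neighborhood; matrix column j in 0..26 counts
  qualifying neighbors, while feature formulas use the dependence size
  j+1 (so small-dependence emphases are finite). DependenceVariance is
  invariant to this shift.
- NGTDM: s_i sums |level - mean in-mask 26-neighbor level| over voxels
  with at least one in-mask neighbor; Coarseness is capped at 1e6 when
  the weighted difference sum is zero; Busyness is 0 when its denominator
  vanishes.
- Degenerate inputs (single gray level, single voxel) map to documented
  0/1 values — e.g. GLCM Correlation 1, Busyness 0 — never NaN, so
  selection never sees missing values.
- First-order Kurtosis is the non-excess moment ratio; Skewness/Kurtosis
  are 0 for constant regions; Entropy/Uniformity reuse the 32-bin
  histogram.

Every builder and all nine model-selected named features are verified
exactly against brute-force enumeration oracles on random instances up to
6^3 voxels with up to 4 gray levels.

## Selection cascade and voting

Stages, each operating on the previous survivors of a training split
standardized to mean 0 / sample SD 1 (statistics fit on the training fold
only): label-correlation screen (point-biserial, two-sided p < 0.05);
univariate logistic (Wald p < 0.10); multivariate logistic (Wald
p < 0.05); L1-penalized logistic at penalty strength 0.05 (objective mean
log-loss + alpha*||w||_1, i.e. C = 1/(n*alpha)), keeping nonzero
coefficients. The "alpha = 0.05" is read as the L1 penalty strength (the
conventional meaning in radiomics platform reports), not a significance
level; the correlation stage is read as a label-association screen
because its stated criterion is a p-value.

Multivariate small-sample handling (open design): candidates are ranked
by univariate p (ties by name), pruned of features correlated > 0.9 with
a better-ranked candidate, capped at n/10 for the joint fit (events per
variable ~10 in a balanced design), and Wald statistics are referred to t
with residual df. This keeps the stage's null retention at its nominal 5%
level, which plain ML Wald violates (7.1% at n=100, p=20). Perfect or
quasi-separation (|beta| > 10 or SE > 20 on z-scored inputs) switches the
fit to Firth's Jeffreys-prior penalized likelihood, which keeps estimates
finite without ridge over-shrinkage.

The cascade runs on each training split of a stratified 5-fold partition
(named seed); a feature's voting count is the number of folds where it
survives all stages, and the final single-model set keeps counts >= 4 of
5. The combined-model set is the union of the two single-model finals,
with combined counts recomputed by rerunning the voting on the pooled
two-sequence table.

With an overwhelming and massively redundant planted signal (the default
6 vs 3 mm texture contrast leaves ~200 features individually able to
separate the classes), no single conditional effect is identifiable in
the joint fit and the cascade can legitimately return an empty final set.
`run_pipeline` then falls back, with a logged warning, to the top-voted
(or, failing that, the top label-correlated) features so the model grid
still runs. The correlation fallback screens on the full data and is
therefore optimistic under the null — on a signal-free cohort the
subsequent grid can show apparent AUC well above chance. It is a rescue
path for degenerate voting, not part of the validated selection
procedure; null-behaviour checks evaluate the grid on label-agnostic
features instead.

## Model grid

8 preprocessors x 13 classifiers = 104 pipelines per model (T2WI, ADC,
combined). Preprocessors: identity, z-score, min-max, and robust-quantile
scaling, each with and without PCA retaining 95% variance (the source
names none; this bank is a reconstruction). Classifiers: logistic
regression, random forest, gradient boosting, k-nearest neighbours, PLS
discriminant analysis (PLS regression on the 0/1 label, midpoint
threshold), regularized QDA (reg_param 0.1), SGD logistic, RBF SVM, plus
decision tree, extra trees, AdaBoost, Gaussian naive Bayes and LDA to
reach the stated 13; hyperparameters are fixed (no inner tuning). All
pipelines share one stratified 5-fold partition (paired comparability for
DeLong); preprocessors are fit on training folds only. Per fold:
Mann-Whitney AUC (ties 1/2) plus accuracy/sensitivity/specificity at the
Youden-optimal threshold; per pipeline: mean metrics and a percentile
bootstrap 95% CI over the fold AUCs. Best pipeline maximizes mean test
AUC, ties broken by mean accuracy then enumeration order; failing
pipelines are logged and excluded.

## Inference

- DeLong paired AUC test from scratch: midrank placement values, the
  structural-components covariance estimator, normal reference. Zero
  difference variance with equal AUCs gives p = 1; with unequal AUCs it
  signals a deterministic difference (p = 0 with a warning). Inestimable
  component covariances (a fold with one positive) are treated as zero
  spread. Type-I error is calibration-tested at 0.05 +- 0.015 over 2000
  null replicates.
- Contingency: Pearson chi-square without continuity correction when all
  expected counts >= 5 (calibrated against the published rows: p = 0.032
  and 0.013 reproduce exactly under the uncorrected statistic), else
  two-sided Fisher exact. One published row (ear creases, 4/24 vs 10/25,
  printed p = 0.048) is not reproducible from its counts under any
  standard test and is deliberately not asserted.
- Group comparison: Shapiro-Wilk gate at 0.05 per group (a
  reconstruction; the source states only the normal/non-normal
  dichotomy); Welch t when both pass, otherwise Mann-Whitney U with the
  tie-corrected normal approximation.

## Problem sizes used in the test suite

The suite runs phantoms on the coarse grid and the end-to-end recovery at
n = 50 per class with a 3-type image bank (original, LoG 2 mm,
wavelet-LLL, 262 features per sequence) — the planted contrasts are fully
expressed there, and the full 15-type/1246-feature bank is exercised on
single subjects and by `scripts/acceptance.py`. Volumetric recovery
(medians, per-class r) is averaged over three independent cohorts because
a single n=50 cohort estimates the weak class's r with SD ~0.11; the
generator chain is unbiased (mean r 0.378/0.708 vs targets 0.38/0.71 over
12 seeds). Null-cohort grids run at n = 20 per class.

## Known limitations

- The feature bank is a reconstruction constrained by the published
  totals (15 image types, 1246 features, the nine named features); the
  original platform's exact bank and discretization are proprietary.
- Phantoms carry no MR physics; absolute feature values are not
  comparable to scanner data, only the pipeline's statistical behaviour.
- The grid's preprocessor bank and 5 of the 13 classifiers are
  conventional completions of a partially specified list.
- Published patient-level AUCs and fold-wise DeLong p-values depend on
  the unavailable cohort and are out of scope by design.
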