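# Methods

## The analysis

The package implements a radiomics classification pipeline for covert
hepatic encephalopathy (CHE) in cirrhosis, built around precuneus ROIs of
pre-aligned 3D T1-weighted brain volumes. The stages are:

1. **ROI extraction.** Volumes and integer masks arrive on a common voxel
   grid (NIfTI-1). ROI voxels are obtained by masked *selection*, not by
   literal multiplication of volume and mask: multiplying would make true
   zero intensities indistinguishable from background, and background must
   not enter any histogram or texture statistic. Masks need at least 27
   voxels, the smallest neighborhood on which 3D texture statistics are
   meaningful.

2. **Feature space.** Each ROI yields exactly 423 features:
   14 first-order intensity statistics, 22 gray-level co-occurrence matrix
   (GLCM) statistics and 11 gray-level run-length matrix (GLRLM) statistics
   on the raw intensities, plus the same 47 statistics on each of the 8
   subbands (LLL … HHH) of a one-level undecimated 3D wavelet transform:
   47 × (1 + 8) = 423, and 4,230 over the 10 precuneus ROIs.

3. **Selection cascade.** On the training portion of a stratified 7:3
   split: (i) a per-feature univariate filter — Shapiro–Wilk normality in
   both groups gates between a pooled-variance t-test and a Mann–Whitney U
   test, keep at p < 0.05, no multiplicity correction; (ii) greedy Spearman
   redundancy pruning at |ρ| > 0.9, scanning features in ascending
   univariate-p order; (iii) LASSO with the squared-error objective
   (1/n)‖y − Xβ‖² + λ‖β‖₁ on z-scored features and 0/1 labels, λ chosen by
   stratified 10-fold cross-validated MSE (minimum rule).

4. **Models.** Radscore = β₀ + Σᵢ βᵢxᵢ with the LASSO coefficients at
   λ_min on standardized features and β₀ the training-label mean. The R
   model is an unpenalized maximum-likelihood logistic refit on the
   signature features; the R-C model is a logistic fit on
   {Radscore, venous ammonia NH₃, Child-Pugh stage (ordinal 1/2/3)}.
   CHE is the positive class. ROC analysis uses the empirical curve, the
   Mann–Whitney AUC, DeLong structural-component variance with a logit-scale
   95% CI, and a Youden-maximal operating threshold chosen on training and
   reused unchanged on testing. Correlated AUCs are compared with the
   paired DeLong z-test.

5. **Reporting.** Nomogram (0–100 point axes; the predictor with the
   largest |coefficient × observed range| spans the full scale; total
   points map to probability through the reconstructed linear predictor),
   decile calibration with the Hosmer–Lemeshow test (df = g − 2), and
   Spearman correlations between signature features / Radscore and the
   clinical variables (NCT-A, DST, NH₃, Child-Pugh, age, sex, education).

## Extraction conventions

These are deliberately pinned so every number is reproducible:

- **Discretization**: 32 equal-width bins over the per-ROI min–max; the
  maximum maps to the top bin; a constant ROI maps to level 1. Fixed bin
  *count* (rather than fixed width) is the natural choice when intensity
  units are arbitrary, as after T1 normalization.
- **Texture matrices**: distance 1, all 13 unique 3D lattice directions,
  per-direction statistics averaged over directions that contain at least
  one pair/run. GLCM is symmetrized and normalized to sum 1; pairs require
  both voxels in-mask. GLRLM runs are maximal same-level sequences along a
  direction, broken by mask boundaries; a hole in the mask splits a run.
- **Degenerate conventions**: for a single-level matrix, correlation, IMC1
  and IMC2 are defined 0; skewness/kurtosis of a constant ROI are 0;
  kurtosis is *excess* kurtosis; variance is the population (1/N) form;
  entropies use log₂.
- **Wavelet**: Haar, one-level stationary (undecimated) transform with
  periodization boundary, so subbands live on the original grid and the
  original mask applies unchanged. Odd axes are edge-padded to even length
  and cropped back. The shortest filter minimizes boundary effects on
  small ROIs.
- **Naming**: `<roi>_<family>_<Feature>[_<subband>]`, e.g.
  `right-Lc1_glcm_InformationalMeasureOfCorrelation1_LLL`, so signature
  feature names map 1:1 to table columns.

## Numerical choices

- **LASSO path**: 100 log-spaced λ values from λ_max = max_j |(2/n)·xⱼᵀ(y−ȳ)|
  down 4 decades, warm-started coordinate descent (numba-JIT inner loop; a
  reference Python loop backs the per-sweep objective monotonicity check).
  Stopping rule: max coefficient change per sweep < 1e-5 on the
  standardized scale (correlated p > n designs stall below this without
  changing any reported quantity); the soft threshold has a 1e-12 relative
  dead-zone so the all-zero solution at λ ≥ λ_max is exact. Non-convergence
  raises; there are no silent partial fits.
- **Folds**: stratified by class, a deterministic function of the seed.
- **Logistic fits**: statsmodels ML with L-BFGS; complete separation is
  detected post hoc and flagged on the model card rather than raised —
  small synthetic cohorts and large signatures can and do separate.
- **Hosmer–Lemeshow**: quantile (decile) bins with ties to the lower bin,
  df = g − 2; bins with expected counts of 0 or n are merged into a
  neighbor with df reduced and the merge count reported.
- **DeLong CI**: logit-transformed, which keeps the interval inside (0,1)
  and asymmetric near the boundary; at AUC exactly 0 or 1 a clipped Wald
  interval is used instead. Degenerate variance in the paired test yields
  p = 1 by convention.

## The synthetic cohort generator

No imaging data are distributed with the study this package operationalizes,
so the generator is a first-class module that emulates the *statistical
structure* the analysis assumes — it is how every downstream stage is
tested.

Each (subject, ROI) volume is a Gaussian random field: white noise smoothed
with an isotropic Gaussian kernel, rescaled to unit marginal variance, then
scaled and shifted. The three class-effect knobs map onto the signature's
feature families: `intensity_shift` moves the histogram (Median, Mean),
`variance_ratio` scales the marginal spread (Variance), and
`smoothness_ratio` scales the autocorrelation length, which GLCM/GLRLM
statistics respond to monotonically. Effects apply only in `effect_rois`
(default: right Lc1 and right PEp, 2 of the 10 ROIs) and only for the CHE
class. Masks are axis-aligned ellipsoids inscribed in the grid, so
run-length handling is exercised across non-box boundaries.

Between-subject biological variability is essential: without it, class
effects measured over thousands of voxels are nearly noise-free and any
cohort separates perfectly, which no patient study shows. Both classes
therefore receive per-subject random modulation of the field mean
(additive sd 40 intensity units), voxel sd (log-normal, sd 0.25 on the log
scale) and smoothing length (log-normal, sd 0.2). The default class
effects (shift 15, variance ratio 1.2, smoothness ratio 1.15) then
correspond to per-feature effect sizes well under one between-subject sd,
placing the default cohort in the moderate-discrimination regime
(testing AUC roughly 0.75–0.9) rather than in a trivial one.

Clinical covariates follow the class-conditional training-set
distributions of the emulated cohort: NH₃ log-normal re-parameterized to
mean±sd 57.43±44.45 (CHE) / 21.36±12.13 μmol/L (nCHE); NCT-A, DST, age and
education normal truncated at zero (63.65±32.00/31.37±7.26 s,
24.51±11.59/38.53±9.18 points, 57±9.98/53.22±8.99 y, 7.95±4.26/9.89±3.03 y);
Child-Pugh categorical with probabilities 8/13/16÷37 (CHE) and 21/12/3÷36
(nCHE); sex M with probability 25/37 and 23/36. Only means/sds and counts
are specified by the source material; all higher moments are modeling
choices, not claims. Per-subject streams derive from the master seed by a
counter scheme (SeedSequence over subject index and a hashed ROI name), so
subjects are independent yet bit-reproducible; the default cohort is
54 CHE / 52 nCHE.

What the generator does **not** emulate: anatomy, skull, registration
error, scanner noise spectra, spatial nonstationarity, or any dependence
between a subject's ROIs beyond the class label. Passing tests therefore
demonstrate the pipeline's correctness and its statistical calibration
under these idealized conditions, not clinical performance on real MRI.

## Behavior worth knowing about

- With the minimum-MSE rule (rather than the 1-SE rule) the 10-fold CV
  tends to choose a small λ and signatures of ~20–35 features at n = 73
  under the default conditions. An unpenalized logistic refit on that many
  features typically separates the training set completely; the fit is
  flagged (`separation_flag`) and training-set metrics should be read
  accordingly. Testing-set metrics remain meaningful.
- Training-derived operating thresholds (Youden) are reused unchanged on
  the testing set; testing sensitivity/specificity are therefore not
  optimized in-sample.
- The univariate filter applies no multiplicity correction by design; at
  4,230 features roughly 5% of pure-noise features pass, which the LASSO
  stage is expected to absorb.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script generate everything at run time.
Demonstration scale: full default cohort (106 subjects), all 10 ROIs on
20³-voxel grids (default grids are 24³); definitional feature counts are
recomputed on a 32³ ROI (per-ROI count) and on 12³ grids (10-ROI total).
Oracle checks run on 5×5×5 masked ROIs against brute-force enumerators;
statistical-calibration suites use 200–500 simulations each.
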