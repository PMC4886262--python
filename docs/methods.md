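# Methods

`serumvar` re-implements, as a tested pipeline with a synthetic-data stand-in,
an analysis of how sex and female hormonal status (oral-contraceptive use,
menstrual-cycle phase, menopause) drive variation in multiplex-immunoassay
serum biomarker panels, and of how ignoring them produces false discoveries in
case-control biomarker studies.

## The synthetic cohort model

Real data of this kind (a two-cohort epidemiological study with a 171-analyte
serum panel) are not publicly deposited, so every stage runs against a
generator with known ground truth. Analytes are log-normal; on the log2 scale

```
log2(conc_ia) = b_a + s_a[g_i] + Σ_c β_ac (x_ic − x̄_c) + ε_ia ,
ε_ia ~ N(0, σ_a²)
```

for sample *i*, analyte *a*, group *g* ∈ {male, follicular, luteal, OC user,
postmenopausal}. Group shifts `s_a[g]` are expressed against the
cycling-female reference, the unweighted mean of the follicular and luteal
groups, so `s_a[follicular] + s_a[luteal] = 0` for every analyte.

Defaults (all configurable through `GeneratorConfig`):

- 171 analytes; 96/171 carry a nonzero male-vs-cycling shift and 66/171 a
  hormonal-status shift, overlapping in 45 analytes (117 affected in total) —
  the affected-set sizes of the study the generator emulates.
- |shift| ~ Uniform(0.1, 1.5) log2 with random sign. Postmenopausal shifts of
  sex-affected analytes take the sign of the male shift (postmenopausal levels
  tend toward male levels); ~5/66 hormone-affected analytes get a small
  follicular/luteal phase difference.
- Residual SD σ_a ~ Uniform(0.2, 0.8) log2 per analyte: biological
  between-subject spread dominating the reported intra-assay CV of ~6%.
- Baselines b_a ~ Uniform(2, 10) log2 (arbitrary per-analyte units).
- Covariates: the study's 16 model covariates plus waist circumference and two
  blood pressures (the 18 classifier covariates). Age and BMI load on half of
  the analytes (≤0.02 and ≤0.04 log2 per unit). Covariate–group confounding
  is on by default — the postmenopausal group is ~25 years older than OC
  users — because such confounding is exactly what the covariate-adjusted
  models must cope with.
- Plates: stratified randomization on group to 26 plates by default. On the
  log2 scale each plate applies an additive shift ~ N(0, 0.15) and scales the
  deviation from the per-analyte mean by a log-normal factor (σ_log = 0.10).
  0.15 log2 ≈ the additive spread implied by an inter-assay CV of 10.6% over
  an intra-assay CV of 5.6% (√(ln(1+0.106²) − ln(1+0.056²))/ln 2 ≈ 0.13).
- Missingness: per-analyte empirical-quantile censoring below (1%) and above
  (0.5%) the limits of quantitation, plus 0.5% low-volume dropout. Censored
  and missing cells carry no value; pre-degradation truth is retained for
  tests only.
- Cohort sizes default to the study layout: discovery 140 males + 34/37/79/57
  females, validation 445/149/211/263/261.

A single user seed fans out to per-stage child generators through
`SeedSequence` keyed on stage labels, so stages are reproducible in isolation.

What the generator does **not** emulate: analyte–analyte correlation beyond
what shared covariate loadings induce, hormone pharmacokinetics, assay drift
within a plate, or non-log-normal tails. Tests passing on this generator
therefore certify the machinery (error control, parameter recovery, batch
correction, classification), not distributional claims about real sera.

## Preprocessing

Fixed order: assay filter → sample filter → imputation → log2 + batch
adjustment → multivariate outlier removal → ordered exclusion cascade.

- **Missingness filters.** An assay is dropped when strictly more than 30% of
  its cells are non-measured (below-/above-LOQ and low-volume all count as
  missing, because the filter precedes the LOQ imputation); then samples with
  strictly more than 30% missing among retained assays are dropped.
- **Imputation**, on the raw concentration scale per analyte: below-LOQ →
  minimum of measured values; above-LOQ → maximum; low-volume → mean.
  Continuous covariates take the mean, discrete ones the mode. Statistics are
  cohort-wide columns, not per group. Measured cells are never altered.
- **Batch adjustment** is the parametric empirical-Bayes location/scale
  model: per-analyte standardization against pooled mean and variance,
  per-plate location (normal prior) and scale (inverse-gamma prior) estimates
  shrunk toward cross-analyte hyper-priors, then adjustment and
  de-standardization. No biological covariates enter the standardization
  model. The implementation is verified against the Bioconductor reference
  implementation to ~1e-15 on a fixture (R-oracle test). A single plate
  reduces to a plain log2 transform.
- **Outliers.** Squared robust Mahalanobis distances from a
  minimum-covariance-determinant fit with subset size h = ⌈(n+d+1)/2⌉,
  flagged above the χ²(d) 0.999 quantile (configurable). When d approaches n
  the distance is computed on the leading principal-component scores (≤10 by
  default). In the pipeline the distances are computed on **group-centered**
  data: the five groups form genuine clusters, and a high-breakdown scatter
  fit on the raw matrix flags entire biological groups (in an early run, the
  whole OC-user group) rather than aberrant samples. Centering by group
  medians before the distance restores the intended behaviour (a few extreme
  samples flagged) while the op itself keeps its plain-matrix contract.
- **Exclusion cascade**, applied after preprocessing, in order: non-fasted;
  pregnant/breastfeeding; non-OC sex-hormone users; hysterectomized; unknown
  hormonal status. A sample matching several rules is removed once, credited
  to the first.

## Per-analyte modeling

For each analyte on the preprocessed log2 scale:

1. **Covariate selection**: bidirectional stepwise search over the 16 model
   covariates under BIC = −2·loglik + k·ln n, with the intercept and the sex
   term forced (selecting away the term under test would leave it undefined).
   Ties prefer deletion, then lexicographic order; rank-deficient candidates
   are skipped with a warning. Selection is re-run per cohort.
2. **Sex model**: OLS of log2 concentration on sex + selected covariates.
   If the smallest Bonferroni-corrected two-sided p-value of the externally
   studentized residuals falls below 0.05, the fit switches to an
   **MM-estimator**: a 50%-breakdown bisquare S-estimate (c = 1.548) supplies
   initial coefficients and a fixed M-scale, followed by a redescending
   bisquare M-step at 95% Gaussian efficiency (c = 4.685). Standard errors
   use the asymptotic covariance scale²·[n/(n−p)]·E[ψ²]/E[ψ′]²·(XᵀX)⁻¹.
   Non-convergence falls back to OLS with a diagnostic flag. The estimator is
   cross-checked against MASS::rlm(method="MM") in an R-oracle test.
3. **Hormonal status**: the 2-level sex term is replaced by the 5-level group
   factor (same covariates). The 3-added-df comparison uses an F-test for OLS
   and a Wald χ²(3) on the added female-subgroup coefficients with the robust
   covariance for MM fits. Four contrasts against the cycling reference
   (mean of follicular and luteal coefficients): OC−cycle, postmenopausal−
   cycle, male−cycle, follicular−luteal, each with a 95% CI from the fit's
   covariance.
4. **FDR**: Benjamini–Hochberg step-up q-values per family (sex p-values
   across analytes; ANOVA p-values; each contrast family), significant at
   q < 0.05. A discovery finding replicates when the validation q < 0.05 and
   the effect sign agrees (sign is not checked for the unsigned ANOVA
   family).

Per-analyte failures become flagged rows; the panel never aborts.

## Group-imbalance Monte-Carlo

The simulation imitates null case-control studies: patient and control groups
of 50 are drawn with replacement from two pools (males vs females, or OC
users vs cycling females) of the preprocessed discovery cohort, with the
pool-A fraction of each group swept over 0, 0.1, …, 1. Per study, a two-sided
Welch t-test per analyte at α = 0.05 counts false discoveries; 1000 studies
per composition pair give the cell mean and its Monte-Carlo SE. Welch rather
than Student is the default because the original analysis environment
defaults to it; a flag restores the pooled-variance variant. No multiplicity
correction is applied inside the simulated studies — the simulated analyst
deliberately uses raw p < 0.05. Per-cell child seeds make cells reproducible
in isolation. The "balanced" summary is the mean over the 11
equal-composition diagonal cells.

A note on calibration: because each draw fixes the composition counts
exactly, both groups of a balanced cell are identical mixtures, and the
between-mode variance of planted shifts inflates the t-denominator without
contributing variance to the mean difference — the balanced diagonal is
therefore *conservative* (below 100·α). How far below depends on the planted
effect-to-noise ratio; with the generator defaults the diagonal averages
≈3.7%, somewhat lower than the ≈4.6% reported on the real cohort, whose
effects are smaller relative to its residual spread. The generator defaults
were fixed a priori and are not tuned to reproduce that figure.

## Classification

A random forest (5000 trees, ⌊√p⌋ candidate features per split, unlimited
depth, bootstrap sampling) labels samples as male / OC user / postmenopausal
/ menstrual-cycle (follicular and luteal merged), trained on the discovery
cohort with the 171 analytes + 18 covariates. Categorical covariates are
one-hot encoded; a categorical's importance is the sum of its indicators'
mean Gini-impurity decreases. Out-of-bag votes give the training-set
confusion matrix and error. A second forest restricted to the ten most
important variables is evaluated on the validation cohort. No class
weighting, hyper-parameter search, or probability calibration.

## Numerical choices and degenerate inputs

- Stepwise BIC uses n·ln(RSS/n) + k·ln n with k the design rank; constant
  terms cancel between candidate models.
- The empirical-Bayes batch iteration stops at relative change 1e-4
  (matching the reference implementation); pooled variances are floored at
  1e-18.
- The S-estimator refines the best 5 of 100 elemental subsets; an exact fit
  of more than half the data returns scale 0 and the M-step is skipped.
  If the M-step worsens the bisquare objective at fixed scale, the S
  coefficients are kept.
- Zero-variance analytes in the t-test count as non-discoveries; Welch df
  falls back to 1 where undefined.
- Singular robust scatters, empty groups, all-filtered matrices, analytes
  with no measured values, k beyond the PCA rank, and single-sample batches
  raise informative errors rather than propagating NaNs.

## Problem sizes used by the test suite

Tests run at the study's discovery scale (171 analytes, 347 samples) where
the property under test concerns that scale (imbalance sweep, classifier),
and at reduced sizes elsewhere (e.g. 500 analytes for coefficient-recovery
checks, 10–20 analytes for pipeline plumbing). The acceptance script runs
the full discovery-scale workflow with 1000 Monte-Carlo studies per grid
cell.

## Known limitations

- The generator's independence of analytes (given covariates) understates
  the correlation of real serum panels; observed false-discovery
  *percentages* are unaffected in expectation, but their Monte-Carlo spread
  on real data would be larger.
- The exact robust-distance cutoff behind the original study's "four samples
  removed" is unstated; the default 0.999 quantile is a choice.
- Whether the original batch adjustment protected biological covariates is
  unstated; this implementation does not.
- The MM covariance uses the simple asymptotic form, not finite-sample
  corrections; contrast CIs from MM fits are asymptotic.
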