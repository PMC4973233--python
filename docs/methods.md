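# Methods

## Setting

Two-sample Mendelian randomization (MR) estimates the causal effect of a
continuous exposure on a disease outcome from two independent GWAS: one
providing per-SNP exposure effects β̂_GP (here: BMI in SD units, 1 SD =
4.65 kg/m²), one providing per-SNP log-odds outcome effects β̂_GD (here:
lung cancer case-control meta-analyses). The causal parameter θ is the
log odds ratio per 1 SD of exposure. The package implements the complete
chain from raw summary-statistics tables to stratified causal estimates,
sensitivity analyses and power.

## Harmonization

Estimation requires (β̂_GP, β̂_GD) pairs expressed for the same physical
allele. Consortium files disagree in two independent ways: the roles of
effect/other allele may be interchanged (label swap: negate β, complement
the allele frequency) and alleles may be reported from the opposite strand
(complement the letters; no numeric change). `harmonize` resolves both by
matching the outcome's allele pair against the exposure's under the four
swap × strand readings, then orients each pair to the exposure-increasing
allele, so every retained instrument has β_GP ≥ 0 — the orientation
MR-Egger requires, and the one that makes a "directional" pleiotropy mean
well defined.

For palindromic SNPs (A/T, C/G) the strand reading is not identifiable
from labels; three policies are provided. The default aligns by allele
frequency: if the two studies' effect-allele frequencies fall on opposite
sides of 0.5 the outcome strand is flipped; SNPs with either frequency in
[0.42, 0.58] (or missing) are dropped as unresolvable. The window and the
drop/keep alternatives are configurable; both behaviors the original
analysis might have used are therefore available.

QC filters: imputation quality strictly greater than 0.6 (SNPs without a
score count as genotyped and are kept), and a named-rsID exclusion list
for sensitivity analyses (e.g. removing a SNP associated with smoking
initiation). Filtering is applied per outcome study before per-SNP
meta-analysis, so each SNP is pooled over exactly the studies in which it
passed QC.

## Estimators

All estimators consume harmonized instruments; all p-values are two-sided
and unadjusted; all CIs are 95%.

**Wald ratio.** θ̂_j = β̂_GD,j/β̂_GP,j with the first-order delta-method
SE σ_GD,j/|β̂_GP,j| (default), or the second-order form adding the
denominator's contribution. First order is the default because the cited
likelihood and weighted-median constructions weight by it.

**IVW.** Fixed-effect precision-weighted mean of the Wald ratios,
algebraically identical to weighted regression of β̂_GD on β̂_GP through
the origin with weights 1/σ²_GD (verified to 1e-10 in tests).

**Likelihood.** The primary estimator maximizes the joint normal
likelihood β̂_GP,j ~ N(ξ_j, σ²_GP,j), β̂_GD,j ~ N(θξ_j, σ²_GD,j) with
independence across SNPs and studies (two-sample design, zero overlap).
The nuisance ξ_j have a closed-form inner maximum, collapsing the profile
log-likelihood to −½ Σ (β̂_GD,j − θβ̂_GP,j)²/(σ²_GD,j + θ²σ²_GP,j); θ̂ is
found by bounded one-dimensional minimization (|θ| ≤ 10, tolerance 1e-8),
making the estimator deterministic. CIs are computed either by inverting
the likelihood-ratio test (profile, default: 2·Δloglik = 3.841, endpoints
by bracketed root-finding) or from the observed-information SE; both are
exposed because either could have produced published intervals, and they
agree to 3 decimals in the high-precision limit (tested).

**Weighted median.** Wald ratios are ordered; the j-th order statistic
represents percentile p_j = Σ_{k≤j} w_(k) − w_(j)/2 of the normalized
inverse-variance weights; the estimate interpolates linearly at p = 1/2
(boundary ratio returned outside [p_1, p_J]; ties broken by stable sort).
The SE is a parametric bootstrap — β̂_GP and β̂_GD resampled from normals
at their reported SEs, weights held fixed at their observed values, the
SD of the replicate medians taken — with a mandatory seed and 10,000
replicates by default. The estimator is consistent while valid
instruments carry more than half of the total weight.

**MR-Egger.** Weighted least squares of β̂_GD on β̂_GP with intercept,
weights 1/σ²_GD. The slope is the pleiotropy-adjusted causal estimate;
the intercept estimates the mean direct effect of the instruments on the
outcome under InSIDE, and its two-sided test (t with J−2 df, multiplicative
residual scale, the standard weighted-lm convention) is the
directional-pleiotropy test. Tests verify the intercept p-value is
uniform under the no-pleiotropy null (KS over 500 replicates).

**Heterogeneity.** Cochran's Q over per-SNP ratios with IVW weights
(df = J−1, χ² upper tail) and I² = max(0, (Q−df)/Q)·100; the same
statistic over stratum-level estimates with 1/SE² weights tests
between-stratum heterogeneity (histology triple, never/ever smokers).

**Meta-analysis.** Fixed-effects inverse-variance pooling (pooled SE
(Σ1/SE²)^−1/2) with Q and I², applied rsID-wise to per-study outcome
effects (after aligning each study's record to a common allele; records
with irreconcilable allele pairs are dropped with a logged reason) and to
study-level score regressions. Inverse-variance rather than sample-size
weighting is used because the downstream estimators need pooled betas
with SEs.

**Genetic score validation.** score_i = Σ_j dosage_ij·β_GP,j — a raw
weighted sum, no centering or rescaling; missing dosages mean-imputed per
SNP; missing weighted SNPs dropped with a warning. Phenotypes are
regressed on the score by OLS adjusting for age, sex and the first 5
principal components (count configurable; the source analyses did not
state one). Listwise deletion for missing phenotypes or covariates.

**Power.** One-tailed normal approximation for a binary outcome:
power = Φ(|ln OR|·√(N·R²·φ(1−φ)) − z_{1−α/2}), and its inversion for the
minimum detectable OR at a target power. At OR = 1 this approximation
returns α/2, its null floor. No continuity correction. The minimum
detectable OR round-trips through the power function to 1e-9 (tested).

## Synthetic-data generator

The generator emulates the study conditions, not merely convenient test
data. Defaults: J = 97 instrument SNPs, instrument R² = 0.027, exposure
GWAS of 339,224 subjects, outcome GWAS of 16,572 cases / 21,480 controls,
MAF uniform on [0.05, 0.5], no LD between instruments (the emulated
instrument was LD-pruned to R² < 0.1).

Per-SNP true exposure effects are drawn as genome-wide significant
discoveries: |ξ_j| = z_gw·σ_GP,j + s·e_j with z_gw = 5.45 (p = 5e-8
two-sided), e_j ~ Exp(1), and the tail scale s solved in closed form so
that Σ 2f_j(1−f_j)ξ_j² equals the R² target exactly. This matters: a
plain normal draw yields many sub-significant SNPs whose orientation
flips on β̂_GP noise, an artifact real (significance-selected)
instruments do not show. If the significance floor alone exceeds the R²
target, the configuration is rejected as unreachable. Signs of ξ are
random; SEs follow the standard GWAS approximations
σ_GP = (2f(1−f)·N_exp)^−1/2 and σ_GD = (2f(1−f)·N·φ(1−φ))^−1/2.

Direct (pleiotropic) effects α_j are defined on the exposure-increasing
allele — the orientation in which a nonzero mean is meaningful — and
applied to a configurable invalid fraction (default 30%) under four
scenarios: none; balanced N(0, τ²); directional N(μ, τ²); and
InSIDE-violated ρ·|ξ_j| + τ·N(0,1). True outcome effects are θξ_j plus
the (re-oriented) α_j; summary statistics are then drawn at the summary
level (normal approximation) rather than via subject-level logistic
simulation, trading exactness at extreme ORs for speed. Allele pairs,
label swaps, strand flips and a configurable palindromic share (default
10%) randomize the presentation so harmonization is genuinely exercised;
a truth record carries everything needed to verify recovery. A
`noise_seed` re-draws only the GWAS sampling noise, giving replicate
datasets from fixed study populations.

Individual-level cohorts draw Hardy-Weinberg genotypes at the same
(f, ξ); BMI is the true score plus small age/sex/PC effects and noise
calibrated so the score explains the R² target of BMI variance (verified
within ±0.005 at n = 50,000); smoking phenotypes (cigarettes/day,
pack-years, cotinine) are independent of the score unless a leak is
configured; case status follows a logistic model on smoking and, through
θ, BMI.

What the generator does **not** emulate: LD structure, population
stratification beyond PC covariates, sample overlap between the two GWAS,
winner's-curse inflation of the exposure effects, and non-collapsibility
subtleties of odds ratios at the individual level. Passing tests
demonstrate correctness of the estimators under the stated measurement
model, not robustness to those real-data features.

## Numerical and design notes

- Optimizer determinism: one-dimensional bounded maximization after exact
  inner profiling; no multi-start needed (the profile objective is smooth
  and, in all tested regimes, unimodal on the bounds).
- Degenerate inputs: zero β_GP is an error for a single Wald ratio;
  all-identical β_GP is a collinearity error for Egger; an all-excluded
  instrument set is legal (logged) for filters but an error for
  estimators, which state their minimum J (2 for likelihood and Q, 3 for
  median and Egger).
- MR-Egger carries a finite-sample attenuation from measurement error in
  β̂_GP (the NOME violation): the slope shrinks by roughly the ratio of
  mean σ²_GP to the weighted variance of β_GP, about 5% of θ under the
  default generator — negligible at small effects, visible (≈0.02 on the
  log-OR scale) at θ = ln(1.45). This is a property of the estimator, not
  of the implementation, and is shared with published Egger analyses.
- The weighted-median bootstrap holds weights fixed across replicates,
  matching the estimator's standard bootstrap; resampling the weights too
  inflates the SE and over-covers.
- Reported odds-ratio intervals exponentiate the log-scale interval;
  every table read back through the package reproduces values to at least
  6 significant digits (written at 10).

## Pipeline

`run_analysis` consumes a YAML config naming the exposure file, per-
stratum outcome study files, QC settings, estimator settings (CI method,
bootstrap size, seed) and power strata. Stratum files are pre-split
inputs — the pipeline does not subset individuals, mirroring analyses
that consumed stratum-level GWAS results. Output: forest-plot tables
(stratum × method with OR, CI, p, SNP count, heterogeneity p, Egger
intercept), between-stratum heterogeneity tests, the sensitivity rerun
under the exclusion list, a power table, and a manifest from which the
run can be repeated byte-identically (tested). The likelihood estimate is
flagged primary; IVW, weighted median and Egger are always computed as
sensitivity analyses.

## Problem sizes in the test suite

Simulation-based tests use 200 replicates at full instrument size
(J = 97) with stratum-scale outcome samples for recovery and robustness
checks, 500 replicates for the Egger-null calibration, 1,000 randomized
records for harmonization enumeration, and 10⁶-point grids / 10⁶ draws
for the brute-force oracles — sizes at which Monte-Carlo error is well
below the asserted tolerances while the whole suite stays interactive.
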