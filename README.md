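# twosample-mr

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
estimating the causal effect of a continuous exposure (body mass index, in
SD units) on a binary outcome (lung cancer risk, overall and by histology,
smoking and sex strata) using published per-SNP association results as
instrumental variables.

The package is for epidemiologists and statistical geneticists who have
per-SNP exposure effects from one consortium GWAS (e.g. the 97-SNP BMI
instrument, effects in SD units where 1 SD = 4.65 kg/m²) and per-SNP
outcome effects from case-control GWAS meta-analyses, and who want the
full analysis chain as reproducible, tested code:

- **summary I/O** — dialect-configurable tab-delimited readers/writers for
  GWAS summary statistics and individual-level dosage/phenotype tables;
- **harmonization** — pairing records per rsID, resolving strand flips and
  label swaps, frequency-aligning or dropping palindromic (A/T, C/G) SNPs,
  orienting every instrument to the exposure-increasing allele, filtering
  on imputation quality (strictly > 0.6) and named-SNP exclusion lists;
- **estimators** — Wald ratios, fixed-effect IVW, a profile-likelihood
  estimator under the bivariate normal measurement model, the weighted
  median (bootstrap SE), MR-Egger regression with its directional
  pleiotropy intercept test, and Cochran's Q / I² heterogeneity among SNP
  and stratum-level estimates;
- **meta-analysis** — fixed-effects inverse-variance pooling of per-SNP
  outcome effects across contributing studies and of study-level
  regressions;
- **score validation** — weighted allele scores on individual-level data,
  regressed on the exposure and on potential confounders (smoking
  phenotypes) with age/sex/principal-component adjustment;
- **power** — binary-outcome MR power and minimum-detectable odds ratio;
- **synthetic data** — a generator for summary-level and individual-level
  datasets with known causal truth and configurable pleiotropy, so the
  whole pipeline is testable end to end without restricted data.

## The model

For SNP *j*, let β̂<sub>GP,j</sub> (SE σ<sub>GP,j</sub>) be the per-allele
effect on the exposure and β̂<sub>GD,j</sub> (SE σ<sub>GD,j</sub>) the
per-allele log odds ratio for the outcome, both for the
exposure-increasing allele. Under the instrumental-variable assumptions
each SNP estimates the causal log odds ratio θ per exposure SD by its Wald
ratio θ̂<sub>j</sub> = β̂<sub>GD,j</sub>/β̂<sub>GP,j</sub>. The primary
estimator maximizes the joint likelihood of the two-sample measurement
model

    β̂_GP,j ~ N(ξ_j,   σ²_GP,j)
    β̂_GD,j ~ N(θ ξ_j, σ²_GD,j)

with the true SNP effects ξ<sub>j</sub> profiled out in closed form;
confidence intervals come from the profile likelihood or the observed
information. IVW is the precision-weighted mean of the Wald ratios; the
weighted median is the 50th percentile of their inverse-variance-weighted
empirical distribution (consistent while valid instruments hold >50% of
the weight); MR-Egger regresses β̂<sub>GD</sub> on β̂<sub>GP</sub> with a
free intercept that estimates average directional pleiotropy. Power for a
case-control outcome uses the normal approximation with non-centrality
|ln OR|·√(N·R²·φ(1−φ)), where φ is the case fraction and R² the exposure
variance explained by the instrument.

## Worked example

Simulate a study-scale dataset (97 genome-wide significant SNPs explaining
2.7% of exposure variance; outcome GWAS of 16,572 cases / 21,480 controls)
with a true OR of 1.45 per SD, harmonize, and run every estimator:

```python
import numpy as np
from twosample_mr import (
    SimulationConfig, simulate_summary_mr, harmonize,
    likelihood_estimate, ivw_estimate, weighted_median_estimate,
    egger_regression, snp_heterogeneity, PowerSpec, min_detectable_or,
)

config = SimulationConfig(theta=np.log(1.45), seed=7)
exposure, outcome, truth = simulate_summary_mr(config)
instruments = harmonize(exposure, outcome)
print(f"{len(instruments)} harmonized instruments (true OR = 1.45)")
for est in (likelihood_estimate(instruments),
            ivw_estimate(instruments),
            weighted_median_estimate(instruments, n_boot=10_000, seed=7)):
    lo, hi = est.or_ci
    print(f"{est.method:>16}: OR {est.odds_ratio:.2f} [{lo:.2f}-{hi:.2f}], "
          f"p = {est.pvalue:.2g}")
egger = egger_regression(instruments)
print(f"    egger_slope: OR {egger.slope.odds_ratio:.2f}, "
      f"intercept {egger.intercept:+.4f} (p = {egger.intercept_pvalue:.2f})")
het = snp_heterogeneity(instruments)
print(f"heterogeneity: Q = {het.q:.1f} on {het.df} df "
      f"(P het = {het.pvalue:.2f}, I^2 = {het.i_squared:.0f}%)")

spec = PowerSpec(n_cases=16_572, n_controls=21_480, r2=0.027)
print(f"min detectable OR at 80% power: {min_detectable_or(spec):.2f}")
```

prints

```
96 harmonized instruments (true OR = 1.45)
      likelihood: OR 1.37 [1.22-1.55], p = 3.6e-07
             ivw: OR 1.37 [1.21-1.55], p = 3.9e-07
 weighted_median: OR 1.53 [1.26-1.84], p = 1.1e-05
    egger_slope: OR 1.66, intercept -0.0059 (p = 0.15)
heterogeneity: Q = 86.8 on 95 df (P het = 0.71, I^2 = 0%)
min detectable OR at 80% power: 1.19
```

One SNP was dropped as an unresolvable palindromic variant (96 of 97
retained). All three causal estimators bracket the simulated truth; the
Egger intercept is compatible with zero (no directional pleiotropy was
injected), and Q shows no excess heterogeneity among the per-SNP
estimates. The last line: a sample of this size can detect an OR of 1.19
per SD with 80% power at α = 0.05.

The same analysis is available from the shell — `twosample-mr simulate`,
`harmonize`, `estimate`, `power`, and `run` (full multi-stratum pipeline
from a YAML config, emitting forest-plot tables, heterogeneity tests, a
power table and a re-runnable manifest). See `twosample-mr --help`.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its calibration, numerical choices, and known limitations.
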