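"""Weighted genetic score construction and instrument-validity regressions.

A valid Mendelian randomization instrument must predict the exposure and be
unrelated to confounders of the exposure-outcome relationship. On
individual-level data the instrument is summarized as a weighted allele
score — per-subject dosages weighted by the per-allele exposure effects —
which is then regressed on measured BMI (should associate strongly) and on
tobacco-exposure phenotypes (should not associate), adjusting for age, sex
and principal components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .summary_io import IndividualDataset

logger = logging.getLogger("twosample_mr")

DEFAULT_COVARIATES = ("age", "sex", "pc")  # "pc" expands to pc1..pcK


class ScoreError(Exception):
    pass


@dataclass
class ScoreAssociation:
    """Regression coefficient of a phenotype on the genetic score."""

    phenotype: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n: int
    study: str = ""

    def to_report_row(self) -> dict:
        return {
            "method": "score_regression",
            "stratum": f"{self.study}:{self.phenotype}" if self.study else self.phenotype,
            "n_snps": self.n,
            "estimate_log": self.slope,
            "se": self.se,
            "ci_low_log": self.ci_low,
            "ci_high_log": self.ci_high,
            "or_": float(np.exp(self.slope)),
            "or_ci_low": float(np.exp(self.ci_low)),
            "or_ci_high": float(np.exp(self.ci_high)),
            "pvalue": self.pvalue,
        }


def build_score(
    data: IndividualDataset,
    weights: Mapping[str, float],
) -> np.ndarray:
    """Per-subject weighted allele score: ``score_i = sum_j dosage_ij * w_j``.

    Weights are the per-allele exposure effects (beta_gp, exposure-SD units)
    on the dosage-coded allele. Weighted SNPs absent from the dosage matrix
    are dropped with a warning; missing dosages are mean-imputed per SNP.
    No frequency centring or rescaling is applied (raw weighted sum).
    """
    present = [rsid for rsid in weights if rsid in data.dosages.columns]
    missing = sorted(set(weights) - set(present))
    if missing:
        logger.warning("build_score: %d weighted SNPs absent from dosages: %s",
                       len(missing), ", ".join(missing[:5]) + ("..." if len(missing) > 5 else ""))
    if not present:
        raise ScoreError("build_score: none of the weighted SNPs are in the dosage matrix")
    dosage = data.dosages[present].astype(float)
    dosage = dosage.fillna(dosage.mean())
    w = np.array([weights[rsid] for rsid in present])
    return dosage.to_numpy() @ w


def score_phenotype_association(
    data: IndividualDataset,
    phenotype: str,
    weights: Mapping[str, float],
    adjust: Sequence[str] = DEFAULT_COVARIATES,
    n_pcs: int = 5,
    score: np.ndarray | None = None,
) -> ScoreAssociation:
    """OLS of a phenotype on the genetic score plus covariates.

    Subjects with a missing phenotype or covariate are excluded listwise.
    The covariate token ``"pc"`` expands to the first ``n_pcs`` principal-
    component columns present. Returns the score coefficient with its 95%
    CI and two-sided p-value.
    """
    if phenotype not in data.phenotypes.columns:
        raise ScoreError(f"phenotype column {phenotype!r} not in dataset")
    if score is None:
        score = build_score(data, weights)

    covariates: list[str] = []
    for token in adjust:
        if token == "pc":
            covariates.extend(data.pc_columns()[:n_pcs])
        else:
            covariates.append(token)
    for cov in covariates:
        if cov not in data.phenotypes.columns:
            raise ScoreError(f"covariate column {cov!r} not in dataset")

    frame = data.phenotypes[[phenotype, *covariates]].copy()
    frame.insert(0, "score", score)
    frame = frame.dropna()
    y = frame[phenotype].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ScoreError(f"phenotype {phenotype!r} is constant")
    X = sm.add_constant(frame[["score", *covariates]].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ScoreError(
            f"rank-deficient design for {phenotype!r}; collinear among "
            f"score/{covariates}"
        )
    fit = sm.OLS(y, X).fit()
    slope, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
    lo, hi = fit.conf_int()[1]
    n = len(frame)
    if n < X.shape[1] + 1:
        raise ScoreError(f"too few subjects ({n}) for {X.shape[1]} parameters")
    logger.info("score ~ %s: slope %.4g (se %.3g, p %.3g, n %d)",
                phenotype, slope, se, p, n)
    return ScoreAssociation(
        phenotype=phenotype,
        slope=float(slope),
        se=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        pvalue=float(p),
        n=n,
        study=data.study,
    )


def validate_instrument(
    datasets: Sequence[IndividualDataset],
    weights: Mapping[str, float],
    phenotypes: Sequence[str] = ("bmi", "cpd", "pack_years", "cotinine"),
    adjust: Sequence[str] = DEFAULT_COVARIATES,
    n_pcs: int = 5,
) -> pd.DataFrame:
    """Per-study score regressions for each phenotype, plus pooled rows.

    Reproduces the forest-plot layout of instrument validation: one row per
    (study, phenotype) and a fixed-effects pooled row per phenotype with Q
    and I^2.
    """
    from .meta_analysis import fixed_effects_pool

    rows = []
    for phenotype in phenotypes:
        per_study = []
        for data in datasets:
            if phenotype not in data.phenotypes.columns:
                continue
            if data.phenotypes[phenotype].dropna().empty:
                continue
            assoc = score_phenotype_association(
                data, phenotype, weights, adjust=adjust, n_pcs=n_pcs
            )
            per_study.append(assoc)
            rows.append({
                "phenotype": phenotype, "study": assoc.study or "study",
                "slope": assoc.slope, "se": assoc.se,
                "ci_low": assoc.ci_low, "ci_high": assoc.ci_high,
                "pvalue": assoc.pvalue, "n": assoc.n, "i_squared": np.nan,
            })
        if len(per_study) > 1:
            meta = fixed_effects_pool([(a.slope, a.se) for a in per_study],
                                      label=phenotype)
            rows.append({
                "phenotype": phenotype, "study": "pooled",
                "slope": meta.pooled, "se": meta.se,
                "ci_low": meta.ci_low, "ci_high": meta.ci_high,
                "pvalue": meta.pvalue, "n": sum(a.n for a in per_study),
                "i_squared": meta.i_squared,
            })
    return pd.DataFrame(rows)
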