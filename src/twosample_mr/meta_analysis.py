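"""Fixed-effects inverse-variance meta-analysis with Cochran's Q and I^2.

Used in two places in the pipeline: pooling study-level genetic-score
regression coefficients, and pooling per-SNP outcome effects (beta_gd)
across the contributing case-control GWAS before causal estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .harmonization import align_to
from .summary_io import VariantAssociation

logger = logging.getLogger("twosample_mr")

Z95 = float(stats.norm.ppf(0.975))


class MetaAnalysisError(Exception):
    pass


@dataclass
class MetaResult:
    """Inverse-variance pooled effect across k studies."""

    pooled: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    q: float
    df: int
    q_pvalue: float
    i_squared: float
    k: int
    label: str = ""

    def to_report_row(self) -> dict:
        return {
            "method": "fixed_effects_meta",
            "stratum": self.label,
            "n_snps": self.k,
            "estimate_log": self.pooled,
            "se": self.se,
            "ci_low_log": self.ci_low,
            "ci_high_log": self.ci_high,
            "or_": float(np.exp(self.pooled)),
            "or_ci_low": float(np.exp(self.ci_low)),
            "or_ci_high": float(np.exp(self.ci_high)),
            "pvalue": self.pvalue,
            "q": self.q,
            "i_squared": self.i_squared,
        }


def fixed_effects_pool(
    effects: Sequence[tuple[float, float]],
    label: str = "",
) -> MetaResult:
    """Pool (estimate, se) pairs by fixed-effects inverse-variance weighting.

    ``pooled = sum(theta_i / se_i^2) / sum(1 / se_i^2)`` with
    ``se = sum(1/se_i^2)^(-1/2)``; heterogeneity by Cochran's Q with k-1
    degrees of freedom and I^2 = max(0, (Q - df)/Q) * 100.
    """
    if not effects:
        raise MetaAnalysisError("fixed_effects_pool: no effects")
    theta = np.array([e[0] for e in effects], dtype=float)
    se = np.array([e[1] for e in effects], dtype=float)
    if np.any(se <= 0):
        raise MetaAnalysisError("fixed_effects_pool: all standard errors must be > 0")
    w = 1.0 / se**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    k = len(effects)
    if k > 1:
        q = float(np.sum(w * (theta - pooled) ** 2))
        df = k - 1
        q_p = float(stats.chi2.sf(q, df))
        i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    else:
        q, df, q_p, i2 = 0.0, 0, 1.0, 0.0
    z = abs(pooled) / pooled_se
    return MetaResult(
        pooled=pooled,
        se=pooled_se,
        ci_low=pooled - Z95 * pooled_se,
        ci_high=pooled + Z95 * pooled_se,
        pvalue=float(2 * stats.norm.sf(z)),
        q=q,
        df=df,
        q_pvalue=q_p,
        i_squared=i2,
        k=k,
        label=label,
    )


def pool_snp_effects(
    per_study: Mapping[str, Sequence[VariantAssociation]],
) -> list[VariantAssociation]:
    """Meta-analyse per-SNP outcome effects across studies, rsid-wise.

    Records for the same rsid are first re-expressed on the allele pair of
    the first study in which the SNP appears (strand flips and label swaps
    resolved as in harmonization); rsids whose allele pairs cannot be
    reconciled across studies are dropped with a logged reason. Each SNP is
    pooled over the studies in which it passed QC, so the contributing-study
    count varies by SNP; per-SNP counts are recorded in the run log.
    """
    order: list[str] = []
    grouped: dict[str, list[tuple[str, VariantAssociation]]] = {}
    for study in per_study:
        for rec in per_study[study]:
            if rec.rsid not in grouped:
                grouped[rec.rsid] = []
                order.append(rec.rsid)
            grouped[rec.rsid].append((study, rec))

    pooled_records: list[VariantAssociation] = []
    for rsid in order:
        entries = grouped[rsid]
        ref = entries[0][1]
        effects: list[tuple[float, float]] = []
        eafs: list[float] = []
        conflict = False
        for _study, rec in entries:
            aligned = align_to(rec, ref.effect_allele, ref.other_allele)
            if aligned is None:
                logger.warning(
                    "pool_snp_effects: %s dropped (allele pair %s/%s conflicts with %s/%s)",
                    rsid, rec.effect_allele, rec.other_allele,
                    ref.effect_allele, ref.other_allele,
                )
                conflict = True
                break
            beta, eaf, _ = aligned
            effects.append((beta, rec.se))
            if eaf is not None:
                eafs.append(eaf)
        if conflict:
            continue
        if len(effects) == 1:
            pooled_beta, pooled_se = effects[0]
            pvalue = ref.pvalue
        else:
            meta = fixed_effects_pool(effects, label=rsid)
            pooled_beta, pooled_se, pvalue = meta.pooled, meta.se, meta.pvalue
        pooled_records.append(
            VariantAssociation(
                rsid=rsid,
                effect_allele=ref.effect_allele,
                other_allele=ref.other_allele,
                beta=pooled_beta,
                se=pooled_se,
                eaf=float(np.mean(eafs)) if eafs else None,
                pvalue=pvalue,
            )
        )
        logger.info("pool_snp_effects: %s pooled over %d studies", rsid, len(effects))
    logger.info("pool_snp_effects: pooled %d SNPs from %d studies",
                len(pooled_records), len(per_study))
    return pooled_records
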