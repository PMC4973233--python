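"""End-to-end analysis: harmonize, pool, estimate, sensitivity, power.

``run_analysis`` drives the whole two-sample MR analysis from a single
declarative config: per outcome stratum (overall, histology subtypes,
smoking/sex strata) it pools the per-study SNP-outcome effects, harmonizes
them with the exposure instrument, and runs the likelihood estimator
(primary) plus the IVW, weighted-median and MR-Egger sensitivity
estimators with per-SNP heterogeneity; across strata it tests
heterogeneity of the causal estimates; it then reruns everything with the
configured SNP exclusion list (pleiotropy sensitivity) and emits a power
table. All outputs are tab-delimited, plus a YAML run manifest sufficient
to re-run the analysis exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import estimators, harmonization, meta_analysis, power_calc, summary_io
from .harmonization import HarmonizedInstrument
from .summary_io import VariantAssociation

logger = logging.getLogger("twosample_mr")

HISTOLOGY_STRATA = ("ad", "sq", "sc")
SMOKING_STRATA = ("never", "ever")


class PipelineError(Exception):
    pass


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    exposure_file: str
    #: stratum -> {study name -> summary-statistics file}
    outcome_files: dict[str, dict[str, str]]
    output_dir: str = "results"
    info_threshold: float = 0.6
    palindromic_policy: str = "frequency"
    exclusion_list: list[str] = field(default_factory=list)
    ci_method: str = "profile"
    n_boot: int = 10_000
    seed: int = 0
    r2: float = 0.027
    #: stratum -> (n_cases, n_controls) for the power table
    power_strata: dict[str, tuple[int, int]] = field(default_factory=dict)
    dialect: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.outcome_files:
            raise PipelineError("at least one outcome stratum is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "power_strata" in raw:
            raw["power_strata"] = {
                k: tuple(v) for k, v in raw["power_strata"].items()
            }
        return cls(**raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["power_strata"] = {k: list(v) for k, v in self.power_strata.items()}
        return yaml.safe_dump(d, sort_keys=False)


@dataclass
class StratumResult:
    stratum: str
    n_snps: int
    estimates: list[estimators.CausalEstimate]
    egger: estimators.EggerResult
    heterogeneity: estimators.HeterogeneityResult


@dataclass
class ResultsBundle:
    strata: dict[str, StratumResult]
    strata_heterogeneity: dict[str, estimators.HeterogeneityResult]
    sensitivity: dict[str, StratumResult]
    power_table: pd.DataFrame | None
    manifest: dict


def _filter_records_by_info(
    records: list[VariantAssociation], threshold: float, label: str
) -> list[VariantAssociation]:
    """Per-study QC: keep records genotyped or imputed with info > threshold."""
    kept = [r for r in records if r.info is None or r.info > threshold]
    logger.info("%s: %d of %d SNPs pass info > %g", label, len(kept), len(records), threshold)
    return kept


def _estimate_stratum(
    stratum: str,
    instruments: list[HarmonizedInstrument],
    config: AnalysisConfig,
) -> StratumResult:
    ests = []
    for builder in (
        lambda: estimators.likelihood_estimate(instruments, ci_method=config.ci_method),
        lambda: estimators.ivw_estimate(instruments),
        lambda: estimators.weighted_median_estimate(
            instruments, n_boot=config.n_boot, seed=config.seed),
    ):
        est = builder()
        est.stratum = stratum
        ests.append(est)
    egger = estimators.egger_regression(instruments)
    egger.slope.stratum = stratum
    ests.append(egger.slope)
    het = estimators.snp_heterogeneity(instruments)
    return StratumResult(
        stratum=stratum, n_snps=len(instruments), estimates=ests,
        egger=egger, heterogeneity=het,
    )


def _harmonized_strata(
    exposure: list[VariantAssociation],
    config: AnalysisConfig,
) -> dict[str, list[HarmonizedInstrument]]:
    out: dict[str, list[HarmonizedInstrument]] = {}
    for stratum, study_files in config.outcome_files.items():
        per_study = {}
        for study, path in study_files.items():
            records = summary_io.read_summary_stats(path, dialect=config.dialect)
            per_study[study] = _filter_records_by_info(
                records, config.info_threshold, f"{stratum}/{study}")
        pooled = meta_analysis.pool_snp_effects(per_study)
        out[stratum] = harmonization.harmonize(
            exposure, pooled, palindromic_policy=config.palindromic_policy)
        logger.info("%s: %d harmonized instruments", stratum, len(out[stratum]))
    return out


def run_analysis(config: AnalysisConfig) -> ResultsBundle:
    """Run the full analysis described by ``config`` and write its outputs."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    exposure = summary_io.read_summary_stats(config.exposure_file, dialect=config.dialect)
    strata_instruments = _harmonized_strata(exposure, config)

    strata: dict[str, StratumResult] = {}
    sensitivity: dict[str, StratumResult] = {}
    errors: list[str] = []
    for stratum, instruments in strata_instruments.items():
        try:
            strata[stratum] = _estimate_stratum(stratum, instruments, config)
        except Exception as exc:  # keep partial results, report context
            errors.append(f"{stratum}/main: {exc}")
            logger.error("stratum %s main analysis failed: %s", stratum, exc)
            continue
        if config.exclusion_list:
            try:
                reduced = harmonization.exclude_snps(instruments, config.exclusion_list)
                sensitivity[stratum] = _estimate_stratum(stratum, reduced, config)
            except Exception as exc:
                errors.append(f"{stratum}/sensitivity: {exc}")
                logger.error("stratum %s sensitivity analysis failed: %s", stratum, exc)

    def primary(stratum: str) -> estimators.CausalEstimate | None:
        res = strata.get(stratum)
        return res.estimates[0] if res else None

    strata_het: dict[str, estimators.HeterogeneityResult] = {}
    for name, members in (("histology", HISTOLOGY_STRATA), ("smoking", SMOKING_STRATA)):
        ests = [primary(s) for s in members]
        ests = [e for e in ests if e is not None]
        if len(ests) >= 2:
            strata_het[name] = estimators.strata_heterogeneity(ests)

    power = None
    if config.power_strata:
        power = power_calc.power_table(config.power_strata, r2=config.r2)
        power.to_csv(out_dir / "power.tsv", sep="\t", index=False, float_format="%.10g")

    bundle = ResultsBundle(
        strata=strata,
        strata_heterogeneity=strata_het,
        sensitivity=sensitivity,
        power_table=power,
        manifest={
            "config": yaml.safe_load(config.to_yaml()),
            "n_snps": {s: r.n_snps for s, r in strata.items()},
            "errors": errors,
        },
    )

    forest_table(bundle).to_csv(out_dir / "estimates.tsv", sep="\t", index=False,
                                float_format="%.10g")
    if sensitivity:
        forest_table(bundle, which="sensitivity").to_csv(
            out_dir / "estimates_sensitivity.tsv", sep="\t", index=False,
            float_format="%.10g")
    if strata_het:
        pd.DataFrame([
            {"comparison": name, "q": h.q, "df": h.df, "pvalue": h.pvalue,
             "i_squared": h.i_squared}
            for name, h in strata_het.items()
        ]).to_csv(out_dir / "strata_heterogeneity.tsv", sep="\t", index=False,
                  float_format="%.10g")
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(bundle.manifest, sort_keys=False))
    logger.info("run_analysis: wrote results to %s", out_dir)
    return bundle


def forest_table(bundle: ResultsBundle, which: str = "main") -> pd.DataFrame:
    """Tabular forest plot: one row per stratum x method.

    Columns carry the OR with its 95% CI, p-value, SNP count, the per-SNP
    heterogeneity p (P het) and, for the Egger rows, the intercept test —
    enough to redraw the forest plots.
    """
    source = bundle.strata if which == "main" else bundle.sensitivity
    if not source:
        raise PipelineError(f"empty results bundle ({which})")
    rows = []
    for stratum, res in source.items():
        for est in res.estimates:
            lo, hi = est.or_ci
            row = {
                "stratum": stratum,
                "method": est.method,
                "primary": est.method == "likelihood",
                "n_snps": est.n_snps,
                "or_": est.odds_ratio,
                "or_ci_low": lo,
                "or_ci_high": hi,
                "estimate_log": est.theta,
                "se": est.se,
                "pvalue": est.pvalue,
                "p_het": res.heterogeneity.pvalue,
                "i_squared": res.heterogeneity.i_squared,
            }
            if est.method == "egger_slope":
                row["egger_intercept"] = res.egger.intercept
                row["egger_intercept_p"] = res.egger.intercept_pvalue
            rows.append(row)
    return pd.DataFrame(rows)
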