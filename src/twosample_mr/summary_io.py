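"""Reading and writing GWAS summary-statistics and individual-level tables.

Every table in the pipeline is plain tab-delimited text with a header row.
Column names vary between consortia (GIANT-style vs METAL-style), so reads
go through a *dialect*: a mapping from the canonical field names used
internally to the column names found in the file.

Canonical fields: ``rsid``, ``effect_allele``, ``other_allele``, ``eaf``,
``beta``, ``se``, ``pvalue``, ``info``, ``n_cases``, ``n_controls``.
Only ``rsid``, ``effect_allele``, ``other_allele``, ``beta`` and ``se`` are
mandatory; missing optional values are empty cells, never zero (zero is a
legal frequency or effect).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("twosample_mr")

VALID_ALLELES = frozenset("ACGT")

#: Default column dialect: canonical name -> file column name.
DEFAULT_DIALECT: dict[str, str] = {
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "info": "info",
    "n_cases": "n_cases",
    "n_controls": "n_controls",
}

MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se")


class SummaryIOError(Exception):
    """Input or configuration problem in a summary-statistics table."""


@dataclass
class VariantAssociation:
    """One SNP's association record from one GWAS.

    ``beta`` is the per-allele effect on the study trait: exposure-SD units
    for an exposure (e.g. BMI) study, log-odds for a case-control outcome
    study. ``info`` is the imputation quality in [0, 1]; ``None`` means the
    SNP was directly genotyped.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    info: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        problems = self.validation_errors()
        if problems:
            raise SummaryIOError(f"{self.rsid}: " + "; ".join(problems))

    def validation_errors(self) -> list[str]:
        out = []
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            out.append(
                f"alleles must be single-base SNP alleles, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        elif self.effect_allele == self.other_allele:
            out.append("effect and other allele are identical")
        if not (self.se > 0 and math.isfinite(self.se)):
            out.append(f"se must be > 0, got {self.se}")
        if not math.isfinite(self.beta):
            out.append(f"beta not finite: {self.beta}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            out.append(f"eaf outside [0,1]: {self.eaf}")
        if self.info is not None and not 0.0 <= self.info <= 1.0:
            out.append(f"info outside [0,1]: {self.info}")
        if self.pvalue is not None and not 0.0 < self.pvalue <= 1.0:
            out.append(f"pvalue outside (0,1]: {self.pvalue}")
        for name in ("n_cases", "n_controls"):
            v = getattr(self, name)
            if v is not None and v < 0:
                out.append(f"{name} negative: {v}")
        return out


@dataclass
class IndividualDataset:
    """Per-subject dosages, phenotypes and covariates for one study.

    ``dosages`` has one column per instrument SNP (values in [0, 2]) and one
    row per subject, aligned with ``phenotypes`` which carries bmi, smoking
    phenotypes (cpd, pack_years, cotinine), case_status, age, sex and
    principal components (columns ``pc1`` .. ``pcK``).
    """

    dosages: pd.DataFrame
    phenotypes: pd.DataFrame
    study: str = ""

    def __post_init__(self) -> None:
        if len(self.dosages) != len(self.phenotypes):
            raise SummaryIOError("dosage and phenotype tables have different row counts")
        d = self.dosages.to_numpy(dtype=float)
        finite = d[np.isfinite(d)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise SummaryIOError("dosage values outside [0, 2]")

    @property
    def rsids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.phenotypes)

    def pc_columns(self) -> list[str]:
        return [c for c in self.phenotypes.columns if c.startswith("pc") and c[2:].isdigit()]


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "nan", "."):
        return None
    return float(value)


def _parse_optional_int(value) -> int | None:
    v = _parse_optional_float(value)
    return None if v is None else int(round(v))


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[VariantAssociation]:
    """Read a tab-delimited summary-statistics file into association records.

    Rows whose mandatory fields cannot be parsed, or that violate record
    invariants (se <= 0, indel alleles, ...), are rejected; each rejection
    is logged with its 1-based data-row number. A missing mandatory column
    is a configuration error; an empty file is an input error.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SummaryIOError(f"{path}: empty file") from None
    if table.empty and table.columns.empty:
        raise SummaryIOError(f"{path}: empty file")
    for canon in MANDATORY_FIELDS:
        if dialect[canon] not in table.columns:
            raise SummaryIOError(
                f"{path}: mandatory column {dialect[canon]!r} (field {canon!r}) missing; "
                f"available: {list(table.columns)}"
            )

    records: list[VariantAssociation] = []
    rejected: list[tuple[int, str]] = []
    for row_number, row in enumerate(table.itertuples(index=False), start=1):
        raw = dict(zip(table.columns, row))
        try:
            rec = VariantAssociation(
                rsid=str(raw[dialect["rsid"]]).strip(),
                effect_allele=str(raw[dialect["effect_allele"]]).strip(),
                other_allele=str(raw[dialect["other_allele"]]).strip(),
                beta=float(raw[dialect["beta"]]),
                se=float(raw[dialect["se"]]),
                eaf=_opt(raw, table.columns, dialect, "eaf"),
                pvalue=_opt(raw, table.columns, dialect, "pvalue"),
                info=_opt(raw, table.columns, dialect, "info"),
                n_cases=_opt(raw, table.columns, dialect, "n_cases", integer=True),
                n_controls=_opt(raw, table.columns, dialect, "n_controls", integer=True),
            )
        except (ValueError, SummaryIOError) as exc:
            rejected.append((row_number, str(exc)))
            continue
        records.append(rec)

    if rejected:
        for row_number, reason in rejected:
            logger.warning("%s: rejected row %d: %s", path.name, row_number, reason)
    logger.info("%s: read %d records, rejected %d rows", path.name, len(records), len(rejected))
    return records


def _opt(raw, columns, dialect, canon, integer=False):
    col = dialect[canon]
    if col not in columns:
        return None
    parse = _parse_optional_int if integer else _parse_optional_float
    return parse(raw[col])


def write_summary_stats(
    records: Sequence[VariantAssociation],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write association records as a tab-delimited file (inverse of read)."""
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    rows = []
    for rec in records:
        row = {}
        for f in dc_fields(VariantAssociation):
            value = getattr(rec, f.name)
            row[dialect[f.name]] = "" if value is None else value
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


RESULTS_COLUMNS = (
    "method",
    "stratum",
    "n_snps",
    "estimate_log",
    "se",
    "ci_low_log",
    "ci_high_log",
    "or_",
    "or_ci_low",
    "or_ci_high",
    "pvalue",
)


def write_results_table(records: Iterable, path: str | Path) -> None:
    """Write causal estimates / pooled results as a tab-delimited table.

    Accepts ``CausalEstimate`` and ``MetaResult`` objects (anything exposing
    the shared reporting attributes via ``to_report_row``). Values written
    with 10 significant digits so a read-back reproduces them well beyond
    the 6-digit contract.
    """
    rows = [rec.to_report_row() for rec in records]
    if not rows:
        raise SummaryIOError("no records to write")
    frame = pd.DataFrame(rows)
    ordered = [c for c in RESULTS_COLUMNS if c in frame.columns]
    ordered += [c for c in frame.columns if c not in ordered]
    frame = frame[ordered]
    try:
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    except OSError as exc:
        raise SummaryIOError(f"cannot write results table to {path}: {exc}") from exc


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_individual_dataset(data: IndividualDataset, path: str | Path) -> None:
    """Write dosages and phenotypes as one wide tab-delimited table."""
    table = pd.concat([data.phenotypes.reset_index(drop=True),
                       data.dosages.reset_index(drop=True)], axis=1)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_individual_dataset(path: str | Path, study: str = "") -> IndividualDataset:
    table = pd.read_csv(path, sep="\t")
    snp_cols = [c for c in table.columns if c.startswith("rs")]
    pheno_cols = [c for c in table.columns if c not in snp_cols]
    return IndividualDataset(
        dosages=table[snp_cols], phenotypes=table[pheno_cols], study=study
    )
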