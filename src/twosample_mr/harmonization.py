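"""Pairing exposure and outcome records and orienting them to a common allele.

The estimators downstream all consume per-SNP pairs (beta_gp, beta_gd): the
per-allele effect on the exposure and on the outcome, expressed for the same
physical allele. Consortium files disagree on which allele is the effect
allele and on which strand alleles are reported, so harmonization must
resolve label swaps (effect/other interchanged) and strand flips (alleles
complemented). Every retained instrument is finally oriented so the effect
allele is the exposure-increasing one (beta_gp >= 0).

Palindromic SNPs (A/T and C/G) carry no strand information in their allele
labels; they are dropped, kept as labelled, or aligned by comparing allele
frequencies between the two studies, per policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .summary_io import VariantAssociation

logger = logging.getLogger("twosample_mr")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf window in which a palindromic SNP's strand cannot be called from
#: frequency: both strand readings give a frequency too close to 0.5.
DEFAULT_EAF_WINDOW = (0.42, 0.58)

PALINDROMIC_POLICIES = ("drop", "frequency", "keep")


class HarmonizationError(Exception):
    pass


@dataclass
class HarmonizedInstrument:
    """Per-SNP exposure/outcome effect pair on a common effect allele.

    After harmonization ``effect_allele`` is the exposure-increasing allele,
    so ``beta_gp >= 0`` for every retained instrument.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_gp: float
    se_gp: float
    beta_gd: float
    se_gd: float
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    palindromic: bool = False
    allele_flipped: bool = False
    excluded_reason: str | None = None

    @property
    def retained(self) -> bool:
        return self.excluded_reason is None


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def _complement_pair(a1: str, a2: str) -> tuple[str, str]:
    return COMPLEMENT[a1], COMPLEMENT[a2]


def align_to(
    record: VariantAssociation,
    effect_allele: str,
    other_allele: str,
) -> tuple[float, float | None, bool] | None:
    """Express ``record``'s effect for the allele pair (effect, other).

    Returns ``(beta, eaf, label_flipped)`` or ``None`` if the allele pairs
    cannot be reconciled by any strand/label combination. For palindromic
    SNPs labels alone cannot distinguish the two physical alleles; this
    helper takes the labels at face value (policy handling is the caller's
    job).
    """
    # Ordered candidates: label-preserving readings first so that for a
    # palindromic SNP (where strand complement collides with label swap)
    # the printed labels are taken at face value.
    candidates = (
        ((record.effect_allele, record.other_allele), False),
        ((record.other_allele, record.effect_allele), True),
        (_complement_pair(record.effect_allele, record.other_allele), False),
        (_complement_pair(record.other_allele, record.effect_allele), True),
    )
    key = (effect_allele, other_allele)
    for pair, flipped in candidates:
        if pair == key:
            if flipped:
                eaf = None if record.eaf is None else 1.0 - record.eaf
                return -record.beta, eaf, True
            return record.beta, record.eaf, False
    return None


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindromic_policy: str = "frequency",
    eaf_window: tuple[float, float] = DEFAULT_EAF_WINDOW,
    drop_excluded: bool = True,
) -> list[HarmonizedInstrument]:
    """Pair exposure and outcome records per rsid on a common effect allele.

    Only rsids present in both studies are returned, in exposure order.
    The outcome effect is re-expressed for the exposure's effect allele
    (negated, with eaf complemented, when the outcome reported the other
    allele); then both studies are oriented to the exposure-increasing
    allele so ``beta_gp >= 0``.

    ``palindromic_policy``: ``"drop"`` excludes A/T and C/G SNPs;
    ``"frequency"`` aligns their strand by allele frequency, excluding SNPs
    whose eaf (either study) falls in ``eaf_window`` or is missing;
    ``"keep"`` trusts the labels as printed.

    With ``drop_excluded=False`` excluded instruments are returned too, with
    ``excluded_reason`` set, for inspection.
    """
    if palindromic_policy not in PALINDROMIC_POLICIES:
        raise HarmonizationError(
            f"unknown palindromic policy {palindromic_policy!r}; "
            f"choose from {PALINDROMIC_POLICIES}"
        )
    outcome_by_rsid = {rec.rsid: rec for rec in outcome}
    shared = [rec for rec in exposure if rec.rsid in outcome_by_rsid]
    if not shared:
        raise HarmonizationError("no shared rsids between exposure and outcome")

    results: list[HarmonizedInstrument] = []
    for exp in shared:
        out = outcome_by_rsid[exp.rsid]
        results.append(
            _harmonize_one(exp, out, palindromic_policy, eaf_window)
        )

    n_excluded = sum(not inst.retained for inst in results)
    for inst in results:
        if not inst.retained:
            logger.warning("harmonize: excluded %s: %s", inst.rsid, inst.excluded_reason)
    logger.info(
        "harmonize: %d shared SNPs, %d retained, %d excluded",
        len(results), len(results) - n_excluded, n_excluded,
    )
    if drop_excluded:
        results = [inst for inst in results if inst.retained]
    return results


def _harmonize_one(
    exp: VariantAssociation,
    out: VariantAssociation,
    palindromic_policy: str,
    eaf_window: tuple[float, float],
) -> HarmonizedInstrument:
    palindromic = is_palindromic(exp.effect_allele, exp.other_allele)

    def build(beta_gd, eaf_out, flipped, excluded=None):
        inst = HarmonizedInstrument(
            rsid=exp.rsid,
            effect_allele=exp.effect_allele,
            other_allele=exp.other_allele,
            beta_gp=exp.beta,
            se_gp=exp.se,
            beta_gd=beta_gd,
            se_gd=out.se,
            eaf_exposure=exp.eaf,
            eaf_outcome=eaf_out,
            palindromic=palindromic,
            allele_flipped=flipped,
            excluded_reason=excluded,
        )
        return _orient_to_exposure_increasing(inst)

    aligned = align_to(out, exp.effect_allele, exp.other_allele)
    if aligned is None:
        return build(out.beta, out.eaf, False, excluded="allele pair irreconcilable "
                     f"({exp.effect_allele}/{exp.other_allele} vs "
                     f"{out.effect_allele}/{out.other_allele})")
    beta_gd, eaf_out, label_flipped = aligned

    if palindromic:
        if palindromic_policy == "drop":
            return build(beta_gd, eaf_out, label_flipped, excluded="palindromic SNP (policy=drop)")
        if palindromic_policy == "frequency":
            lo, hi = eaf_window
            if exp.eaf is None or eaf_out is None:
                return build(beta_gd, eaf_out, label_flipped,
                             excluded="palindromic SNP without eaf in both studies")
            if lo <= exp.eaf <= hi or lo <= eaf_out <= hi:
                return build(beta_gd, eaf_out, label_flipped,
                             excluded=f"palindromic SNP with ambiguous eaf "
                                      f"(window {lo}-{hi})")
            # Opposite minor alleles between studies => the outcome labels
            # are on the other strand: flip to the frequency-consistent
            # reading of the two possible strand configurations.
            if (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:
                beta_gd = -beta_gd
                eaf_out = 1.0 - eaf_out
                label_flipped = True
        # policy == "keep": take labels at face value

    return build(beta_gd, eaf_out, label_flipped)


def _orient_to_exposure_increasing(inst: HarmonizedInstrument) -> HarmonizedInstrument:
    """Swap allele roles so the effect allele increases the exposure."""
    if inst.beta_gp < 0:
        return replace(
            inst,
            effect_allele=inst.other_allele,
            other_allele=inst.effect_allele,
            beta_gp=-inst.beta_gp,
            beta_gd=-inst.beta_gd,
            eaf_exposure=None if inst.eaf_exposure is None else 1.0 - inst.eaf_exposure,
            eaf_outcome=None if inst.eaf_outcome is None else 1.0 - inst.eaf_outcome,
        )
    return inst


def filter_by_info(
    instruments: Sequence[HarmonizedInstrument],
    info_by_rsid: Mapping[str, float | None],
    threshold: float = 0.6,
) -> list[HarmonizedInstrument]:
    """Keep SNPs whose imputation quality is strictly above ``threshold``.

    SNPs absent from ``info_by_rsid`` or with a ``None`` score are treated
    as directly genotyped and kept. The comparison is strict: a SNP with
    info exactly at the threshold is excluded.
    """
    if not 0.0 <= threshold <= 1.0:
        raise HarmonizationError(f"info threshold outside [0,1]: {threshold}")
    kept: list[HarmonizedInstrument] = []
    for inst in instruments:
        info = info_by_rsid.get(inst.rsid)
        if info is None or info > threshold:
            kept.append(inst)
        else:
            logger.info("filter_by_info: excluded %s (info %.3g <= %.3g)",
                        inst.rsid, info, threshold)
    logger.info("filter_by_info: %d of %d SNPs retained at threshold %g",
                len(kept), len(instruments), threshold)
    if not kept:
        logger.warning("filter_by_info: no SNPs retained")
    return kept


def exclude_snps(
    instruments: Sequence[HarmonizedInstrument],
    rsids: Iterable[str],
) -> list[HarmonizedInstrument]:
    """Remove named SNPs (sensitivity analyses, e.g. smoking-associated SNPs)."""
    rsid_set = set(rsids)
    present = {inst.rsid for inst in instruments}
    for rsid in sorted(rsid_set - present):
        logger.warning("exclude_snps: %s not present in instrument set", rsid)
    kept = [inst for inst in instruments if inst.rsid not in rsid_set]
    logger.info("exclude_snps: removed %d of %d SNPs", len(instruments) - len(kept),
                len(instruments))
    if not kept:
        logger.warning("exclude_snps: all instruments excluded")
    return kept


def read_exclusion_list(path: str | Path) -> list[str]:
    """Read a plain-text exclusion list, one rsid per line, '#' comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
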