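"""Synthetic two-sample MR datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
GIANT-scale exposure GWAS providing per-SNP effects in exposure-SD units, a
case-control outcome GWAS providing log-odds effects, and individual-level
cohorts for score validation. Defaults mirror the study conditions of the
lung-cancer analysis: a 97-SNP instrument explaining 2.7% of exposure
variance, an exposure GWAS of 339,224 subjects, and an outcome sample of
16,572 cases / 21,480 controls.

Summary statistics are generated directly at the summary level under the
standard GWAS approximations

    se_gp_j = 1 / sqrt(2 f_j (1-f_j) * N_exposure)
    se_gd_j = 1 / sqrt(2 f_j (1-f_j) * N_outcome * phi * (1-phi))

with true per-SNP exposure effects xi_j rescaled so the instrument explains
exactly ``r2_target`` of exposure variance, and true outcome effects
``theta * xi_j + alpha_j`` where alpha_j is the direct (pleiotropic) effect
under the configured scenario. Allele labels, strands and effect-allele
choices are randomized to exercise harmonization; the returned truth record
carries everything needed to verify recovery.

Individual-level cohorts draw Hardy-Weinberg genotypes (no LD between
instrument SNPs — the instrument variants are mutually independent) and
build BMI from the genetic score, age/sex/PC covariate effects and noise
calibrated so the score explains ``r2_target`` of BMI variance; smoking
phenotypes are generated independent of the score unless a leak is
requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .summary_io import (
    IndividualDataset,
    VariantAssociation,
    write_individual_dataset,
    write_summary_stats,
)

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
NONPALINDROMIC_PAIRS = tuple(
    (a, b) for a in BASES for b in BASES if b not in (a, COMPLEMENT[a])
)

BMI_SD_KGM2 = 4.65  # kg/m^2 per exposure SD


class SimulationError(Exception):
    pass


@dataclass
class Pleiotropy:
    """Direct-effect scenario for the invalid instrument subset.

    Direct effects are defined on the exposure-increasing allele (the
    orientation every estimator sees after harmonization) — "directional"
    would otherwise average out under random allele orientation.

    kind "none": alpha_j = 0 everywhere. "balanced": alpha_j ~ N(0, tau^2)
    (zero mean, InSIDE holds). "directional": alpha_j ~ N(mu, tau^2)
    (nonzero mean, InSIDE holds). "inside_violated": alpha_j = rho * |xi_j|
    + tau * N(0,1), correlating direct effects with instrument strength.
    """

    kind: str = "none"
    mu: float = 0.0
    tau: float = 0.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional", "inside_violated"):
            raise SimulationError(f"unknown pleiotropy kind {self.kind!r}")
        if self.tau < 0:
            raise SimulationError("tau must be >= 0")


@dataclass
class SimulationConfig:
    """Full specification of a synthetic two-sample MR dataset."""

    theta: float = 0.0
    j_snps: int = 97
    r2_target: float = 0.027
    n_exposure_gwas: int = 339_224
    n_cases: int = 16_572
    n_controls: int = 21_480
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    invalid_fraction: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: minimum |xi|/se_gp: instrument SNPs are genome-wide significant
    #: discoveries (z for p = 5e-8 two-sided)
    gw_threshold_z: float = 5.45
    palindromic_fraction: float = 0.10
    label_swap_fraction: float = 0.30
    strand_flip_fraction: float = 0.30
    info_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j_snps < 1:
            raise SimulationError("j_snps must be >= 1")
        if not 0.0 < self.r2_target < 1.0:
            raise SimulationError(f"r2_target must be in (0,1), got {self.r2_target}")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise SimulationError("invalid_fraction must be in [0,1]")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise SimulationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")


def _draw_instrument(config: SimulationConfig, rng: np.random.Generator):
    """Allele frequencies and true exposure effects scaled to r2_target.

    Instrument SNPs are genome-wide significant discoveries, so effect
    magnitudes are drawn as significance threshold plus an exponential
    tail, |xi_j| = z_gw * se_gp_j + s * e_j with e_j ~ Exp(1), and the
    tail scale s is solved (closed-form quadratic) so the instrument
    explains exactly ``r2_target`` of exposure variance. If the threshold
    contribution alone already exceeds r2_target, the target is
    unreachable for this (j_snps, maf_range, n_exposure) combination.
    """
    f = rng.uniform(*config.maf_range, size=config.j_snps)
    het = 2.0 * f * (1.0 - f)  # per-SNP heterozygosity
    se_gp = 1.0 / np.sqrt(het * config.n_exposure_gwas)
    t = config.gw_threshold_z * se_gp
    e = rng.exponential(1.0, size=config.j_snps)
    # sum het*(t + s*e)^2 = r2  =>  A s^2 + B s + C = 0
    A = np.sum(het * e**2)
    B = 2.0 * np.sum(het * t * e)
    C = np.sum(het * t**2) - config.r2_target
    if C >= 0:
        raise SimulationError(
            f"r2_target={config.r2_target} unreachable: {config.j_snps} "
            f"genome-wide significant SNPs already explain "
            f"{np.sum(het * t**2):.4f} at the significance floor"
        )
    s = (-B + np.sqrt(B**2 - 4 * A * C)) / (2 * A)
    xi = (t + s * e) * rng.choice([-1.0, 1.0], size=config.j_snps)
    return f, xi


def _draw_alpha(config: SimulationConfig, xi: np.ndarray, rng: np.random.Generator):
    """Per-SNP direct effects (exposure-increasing orientation)."""
    alpha = np.zeros(config.j_snps)
    scen = config.pleiotropy
    if scen.kind == "none":
        return alpha, np.array([], dtype=int)
    n_invalid = int(round(config.invalid_fraction * config.j_snps))
    invalid = rng.choice(config.j_snps, size=n_invalid, replace=False)
    invalid.sort()
    if scen.kind == "balanced":
        alpha[invalid] = rng.normal(0.0, scen.tau, size=n_invalid)
    elif scen.kind == "directional":
        alpha[invalid] = rng.normal(scen.mu, scen.tau, size=n_invalid)
    else:  # inside_violated
        alpha[invalid] = scen.rho * np.abs(xi[invalid]) + rng.normal(0.0, scen.tau, size=n_invalid)
    return alpha, invalid


def simulate_summary_mr(
    config: SimulationConfig,
    noise_seed: int | None = None,
) -> tuple[list[VariantAssociation], list[VariantAssociation], dict]:
    """Generate paired exposure/outcome summary statistics plus ground truth.

    The exposure records are oriented to the drawn effect allele as a
    consortium would publish them (effects of either sign); the outcome
    records are randomly label-swapped and strand-flipped so harmonization
    is exercised. The truth dict carries theta, f, xi, alpha, the invalid
    subset, the per-SNP presentation flags and the analytic SEs.

    ``noise_seed`` re-draws only the GWAS sampling noise while keeping the
    instrument truth (f, xi, alpha, alleles) fixed — replicate datasets
    from the same underlying study populations.
    """
    rng = np.random.default_rng(config.seed)
    f, xi = _draw_instrument(config, rng)
    alpha, invalid = _draw_alpha(config, xi, rng)
    noise_rng = rng if noise_seed is None else np.random.default_rng(
        [config.seed, 1_000_003, noise_seed])

    n_total = config.n_cases + config.n_controls
    phi = config.n_cases / n_total
    se_gp = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * config.n_exposure_gwas)
    se_gd = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_total * phi * (1.0 - phi))

    beta_gp_hat = noise_rng.normal(xi, se_gp)
    # alpha lives on the exposure-increasing allele; re-express it on the
    # published allele, whose exposure effect is xi (of either sign)
    beta_gd_true = config.theta * xi + np.sign(xi) * alpha
    beta_gd_hat = noise_rng.normal(beta_gd_true, se_gd)

    rsids = [f"rs{1_000_000 + k}" for k in range(config.j_snps)]
    is_palindromic = rng.random(config.j_snps) < config.palindromic_fraction
    label_swap = rng.random(config.j_snps) < config.label_swap_fraction
    strand_flip = rng.random(config.j_snps) < config.strand_flip_fraction
    eaf_outcome = np.clip(f + rng.normal(0.0, 0.005, size=config.j_snps), 0.001, 0.999)
    if config.info_range is not None:
        info = rng.uniform(*config.info_range, size=config.j_snps)
    else:
        info = np.full(config.j_snps, np.nan)

    exposure: list[VariantAssociation] = []
    outcome: list[VariantAssociation] = []
    pairs = []
    for k in range(config.j_snps):
        if is_palindromic[k]:
            ea, oa = PALINDROMIC_PAIRS[rng.integers(len(PALINDROMIC_PAIRS))]
        else:
            ea, oa = NONPALINDROMIC_PAIRS[rng.integers(len(NONPALINDROMIC_PAIRS))]
        pairs.append((ea, oa))
        exposure.append(VariantAssociation(
            rsid=rsids[k], effect_allele=ea, other_allele=oa,
            beta=float(beta_gp_hat[k]), se=float(se_gp[k]), eaf=float(f[k]),
        ))
        # Outcome presentation: optionally swap labels and/or report the
        # complementary strand. For palindromic SNPs a strand flip changes
        # which physical allele the printed label names, so beta/eaf follow
        # the label; this is exactly the ambiguity harmonization resolves.
        o_ea, o_oa = ea, oa
        o_beta, o_eaf = float(beta_gd_hat[k]), float(eaf_outcome[k])
        if label_swap[k]:
            o_ea, o_oa = o_oa, o_ea
            o_beta, o_eaf = -o_beta, 1.0 - o_eaf
        if strand_flip[k]:
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        outcome.append(VariantAssociation(
            rsid=rsids[k], effect_allele=o_ea, other_allele=o_oa,
            beta=o_beta, se=float(se_gd[k]), eaf=o_eaf,
            info=None if np.isnan(info[k]) else float(info[k]),
            n_cases=config.n_cases, n_controls=config.n_controls,
        ))

    truth = {
        "theta": config.theta,
        "rsids": rsids,
        "f": f, "xi": xi, "alpha": alpha,
        "invalid": invalid,
        "se_gp": se_gp, "se_gd": se_gd,
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "palindromic": is_palindromic,
        "label_swap": label_swap,
        "strand_flip": strand_flip,
    }
    return exposure, outcome, truth


def simulate_multi_study_outcome(
    config: SimulationConfig,
    study_sizes: dict[str, tuple[int, int]],
) -> tuple[list[VariantAssociation], dict[str, list[VariantAssociation]], dict]:
    """One exposure study and several outcome studies sharing the same truth.

    Each outcome study gets its own sampling noise at its own sample size
    and its own imputation-quality scores, emulating the per-study GWAS
    whose effects are meta-analysed before causal estimation.
    """
    exposure, _, truth = simulate_summary_mr(config)
    per_study: dict[str, list[VariantAssociation]] = {}
    for snum, (study, (n_cases, n_controls)) in enumerate(study_sizes.items(), start=1):
        rng = np.random.default_rng([config.seed, snum])
        n_total = n_cases + n_controls
        phi = n_cases / n_total
        se_gd = 1.0 / np.sqrt(2.0 * truth["f"] * (1.0 - truth["f"]) * n_total * phi * (1.0 - phi))
        beta_true = config.theta * truth["xi"] + np.sign(truth["xi"]) * truth["alpha"]
        beta_hat = rng.normal(beta_true, se_gd)
        info = (rng.uniform(*config.info_range, size=config.j_snps)
                if config.info_range is not None else None)
        records = []
        for k, rsid in enumerate(truth["rsids"]):
            records.append(VariantAssociation(
                rsid=rsid,
                effect_allele=truth["effect_allele"][k],
                other_allele=truth["other_allele"][k],
                beta=float(beta_hat[k]), se=float(se_gd[k]),
                eaf=float(truth["f"][k]),
                info=None if info is None else float(info[k]),
                n_cases=n_cases, n_controls=n_controls,
            ))
        per_study[study] = records
    return exposure, per_study, truth


def simulate_individual_cohort(
    config: SimulationConfig,
    n_subjects: int,
    smoking_independent: bool = True,
    smoking_leak: float = 0.0,
    n_pcs: int = 5,
    study: str = "synthetic",
) -> IndividualDataset:
    """Individual-level genotype/phenotype table for score validation.

    BMI (kg/m^2) is built from the true genetic score (which explains
    ``r2_target`` of BMI variance), small age/sex/PC effects, and normal
    noise; the exposure SD is 4.65 kg/m^2. Smoking phenotypes (cpd,
    pack_years, cotinine) are independent of the score when
    ``smoking_independent``; otherwise ``smoking_leak`` cigarettes/day per
    SD of genetic score leak through. Case status follows a logistic model
    on smoking and, through theta, on BMI.
    """
    if n_subjects < 100:
        raise SimulationError("n_subjects must be >= 100")
    rng_instr = np.random.default_rng(config.seed)
    f, xi = _draw_instrument(config, rng_instr)
    rsids = [f"rs{1_000_000 + k}" for k in range(config.j_snps)]

    rng = np.random.default_rng([config.seed, 7])
    g = rng.binomial(2, f, size=(n_subjects, config.j_snps)).astype(float)
    score = g @ xi
    score_centered = score - np.sum(2 * f * xi)  # expected score

    age = rng.normal(60.0, 8.0, size=n_subjects)
    sex = rng.integers(0, 2, size=n_subjects)
    pcs = rng.normal(size=(n_subjects, n_pcs))

    b_age, b_sex, b_pc = 0.10, 0.10, 0.02
    covariate_part = (
        b_age * (age - 60.0) / 8.0
        + b_sex * (sex - 0.5)
        + pcs @ np.full(n_pcs, b_pc)
    )
    var_cov = b_age**2 + b_sex**2 * 0.25 + n_pcs * b_pc**2
    var_noise = max(1.0 - config.r2_target - var_cov, 1e-6)
    bmi_sd = score_centered + covariate_part + rng.normal(0.0, np.sqrt(var_noise), n_subjects)
    bmi = 25.0 + BMI_SD_KGM2 * bmi_sd

    score_sd = np.std(score) if np.std(score) > 0 else 1.0
    leak = 0.0 if smoking_independent else smoking_leak
    cpd = np.clip(rng.normal(15.0, 8.0, n_subjects), 0.0, None)
    cpd = cpd + leak * (score - score.mean()) / score_sd
    years_smoked = np.clip(rng.normal(30.0, 10.0, n_subjects), 0.0, None)
    pack_years = cpd / 20.0 * years_smoked
    cotinine = np.clip(10.0 * cpd + rng.normal(0.0, 60.0, n_subjects), 0.0, None)

    logit = -0.2 + 0.04 * (cpd - cpd.mean()) + config.theta * bmi_sd
    case_status = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit)))

    phenotypes = pd.DataFrame({
        "bmi": bmi,
        "cpd": cpd,
        "pack_years": pack_years,
        "cotinine": cotinine,
        "case_status": case_status,
        "age": age,
        "sex": sex,
        **{f"pc{i + 1}": pcs[:, i] for i in range(n_pcs)},
    })
    dosages = pd.DataFrame(g, columns=rsids)
    return IndividualDataset(dosages=dosages, phenotypes=phenotypes, study=study)


DEFAULT_STUDY_SIZES = {
    "tricl": (11_348, 15_861),
    "epic": (1_437, 1_453),
    "axiom": (3_456, 3_850),
}


def write_study_fixture(
    config: SimulationConfig,
    directory: str | Path,
    study_sizes: dict[str, tuple[int, int]] | None = None,
    n_subjects: int = 2_000,
) -> Path:
    """Emit a ready-made synthetic study directory.

    Contents: ``exposure.tsv``, one ``outcome_<study>.tsv`` per outcome
    study, ``individuals.tsv`` and ``truth.json``. All tables use the
    default summary-statistics dialect.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study_sizes = study_sizes or DEFAULT_STUDY_SIZES
    exposure, per_study, truth = simulate_multi_study_outcome(config, study_sizes)
    write_summary_stats(exposure, directory / "exposure.tsv")
    for study, records in per_study.items():
        write_summary_stats(records, directory / f"outcome_{study}.tsv")
    cohort = simulate_individual_cohort(config, n_subjects=n_subjects)
    write_individual_dataset(cohort, directory / "individuals.tsv")
    serializable = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in truth.items()
    }
    (directory / "truth.json").write_text(json.dumps(serializable, indent=1))
    return directory
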