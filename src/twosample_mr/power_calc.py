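"""Statistical power for Mendelian randomization with a binary outcome.

Follows the normal-approximation approach of Burgess for case-control MR:
the test statistic for the causal log odds ratio ``b = ln(OR)`` per SD of
exposure has non-centrality

    ncp = |b| * sqrt(N * R2 * phi * (1 - phi))

where ``N`` is the total sample size, ``phi`` the case fraction and ``R2``
the fraction of exposure variance explained by the instrument. Power at
two-sided level alpha is ``Phi(ncp - z_{1-alpha/2})`` (one-tailed
approximation, no continuity correction); inverting gives the minimum
detectable odds ratio at a target power,

    OR_min = exp((z_{1-alpha/2} + z_power) / sqrt(N * R2 * phi * (1-phi))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class PowerError(Exception):
    pass


@dataclass
class PowerSpec:
    """Inputs of an MR power calculation for a case-control outcome."""

    n_cases: int
    n_controls: int
    r2: float = 0.027
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise PowerError("n_cases and n_controls must be positive")
        if not 0.0 < self.r2 < 1.0:
            raise PowerError(f"r2 must be in (0,1), got {self.r2}")
        if not 0.0 < self.alpha < 1.0:
            raise PowerError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0.0 < self.target_power < 1.0:
            raise PowerError(f"target_power must be in (0,1), got {self.target_power}")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total

    @property
    def _sqrt_information(self) -> float:
        phi = self.case_fraction
        return float(np.sqrt(self.n_total * self.r2 * phi * (1.0 - phi)))


def mr_power(spec: PowerSpec, odds_ratio: float) -> float:
    """Power to detect ``odds_ratio`` per 1 SD of exposure at level alpha.

    Symmetric in the effect direction: power(OR) == power(1/OR). At OR = 1
    the one-tailed approximation returns alpha/2 (the null rejection floor).
    """
    if odds_ratio <= 0:
        raise PowerError(f"odds_ratio must be > 0, got {odds_ratio}")
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = abs(np.log(odds_ratio)) * spec._sqrt_information
    return float(stats.norm.cdf(ncp - z_alpha))


def min_detectable_or(spec: PowerSpec) -> float:
    """Smallest odds ratio > 1 detectable at ``spec.target_power``.

    The detectable protective effect is the reciprocal, ``1 / OR_min``.
    Round-trips through :func:`mr_power` to the target power.
    """
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_power = stats.norm.ppf(spec.target_power)
    return float(np.exp((z_alpha + z_power) / spec._sqrt_information))


def power_table(strata: dict[str, tuple[int, int]], r2: float = 0.027,
                alpha: float = 0.05, target_power: float = 0.80,
                odds_ratios: tuple[float, ...] = ()) -> "pd.DataFrame":
    """Per-stratum minimum detectable OR (and optional power at given ORs)."""
    import pandas as pd

    rows = []
    for stratum, (n_cases, n_controls) in strata.items():
        spec = PowerSpec(n_cases=n_cases, n_controls=n_controls, r2=r2,
                         alpha=alpha, target_power=target_power)
        row = {
            "stratum": stratum,
            "n_cases": n_cases,
            "n_controls": n_controls,
            "min_detectable_or": min_detectable_or(spec),
            "target_power": target_power,
        }
        for odds_ratio in odds_ratios:
            row[f"power_at_or_{odds_ratio:g}"] = mr_power(spec, odds_ratio)
        rows.append(row)
    return pd.DataFrame(rows)
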