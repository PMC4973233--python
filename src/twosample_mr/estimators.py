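"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume harmonized instruments: per-SNP pairs
``(beta_gp, se_gp)`` — the per-allele effect on the exposure in SD units —
and ``(beta_gd, se_gd)`` — the per-allele log-odds effect on the outcome —
expressed for the same (exposure-increasing) allele. The causal parameter
``theta`` is the log odds ratio of the outcome per 1 SD increase in the
exposure.

Estimators
----------
wald_ratio
    Per-SNP ratio ``beta_gd / beta_gp`` with a delta-method standard error.
ivw_estimate
    Fixed-effect inverse-variance weighted average of the Wald ratios;
    algebraically a weighted regression of beta_gd on beta_gp through the
    origin with weights ``1/se_gd**2``.
likelihood_estimate
    Maximum-likelihood fit of the bivariate normal measurement model

        beta_gp_hat_j ~ N(xi_j, se_gp_j**2)
        beta_gd_hat_j ~ N(theta * xi_j, se_gd_j**2)

    with the per-SNP true effects ``xi_j`` profiled out in closed form;
    this accounts for measurement error in the SNP-exposure effects, which
    IVW ignores. Confidence intervals by profile likelihood or by the
    observed-information (Wald) standard error.
weighted_median_estimate
    The 50th percentile of the inverse-variance weighted empirical
    distribution of ordered Wald ratios; consistent when valid instruments
    carry more than half of the total weight. SE by parametric bootstrap.
egger_regression
    Weighted linear regression of beta_gd on beta_gp *with* an intercept;
    the intercept estimates average directional pleiotropy and its test is
    reported alongside the pleiotropy-adjusted slope.

Heterogeneity among per-SNP causal estimates (Cochran's Q, I^2) and among
stratum-level estimates is provided by ``snp_heterogeneity`` and
``strata_heterogeneity``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .harmonization import HarmonizedInstrument

logger = logging.getLogger("twosample_mr")

Z95 = float(stats.norm.ppf(0.975))
#: chi-square(1) 95% quantile: profile-likelihood CI cutoff on 2*delta-loglik.
CHI2_95 = float(stats.chi2.ppf(0.95, df=1))

METHODS = ("wald", "ivw", "likelihood", "weighted_median", "egger_slope")


class EstimationError(Exception):
    pass


@dataclass
class CausalEstimate:
    """A causal log-odds-ratio estimate per 1 SD of exposure, with 95% CI."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    stratum: str = ""

    def __post_init__(self) -> None:
        if not self.ci_low <= self.theta <= self.ci_high:
            raise EstimationError(
                f"{self.method}: CI [{self.ci_low}, {self.ci_high}] does not "
                f"bracket theta={self.theta}"
            )

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_report_row(self) -> dict:
        lo, hi = self.or_ci
        return {
            "method": self.method,
            "stratum": self.stratum,
            "n_snps": self.n_snps,
            "estimate_log": self.theta,
            "se": self.se,
            "ci_low_log": self.ci_low,
            "ci_high_log": self.ci_high,
            "or_": self.odds_ratio,
            "or_ci_low": lo,
            "or_ci_high": hi,
            "pvalue": self.pvalue,
        }


@dataclass
class EggerResult:
    """MR-Egger slope (causal estimate) and intercept (pleiotropy test)."""

    slope: CausalEstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


@dataclass
class HeterogeneityResult:
    """Cochran's Q with degrees of freedom, p-value and I^2 (percent)."""

    q: float
    df: int
    pvalue: float
    i_squared: float


def _wald_pvalue(theta: float, se: float) -> float:
    if se == 0:
        return 0.0 if theta != 0 else 1.0
    return float(2 * stats.norm.sf(abs(theta) / se))


def _wald_estimate(method, theta, se, n_snps, stratum="") -> CausalEstimate:
    return CausalEstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z95 * se),
        ci_high=float(theta + Z95 * se),
        pvalue=_wald_pvalue(theta, se),
        n_snps=n_snps,
        stratum=stratum,
    )


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    bgp = np.array([i.beta_gp for i in instruments], dtype=float)
    sgp = np.array([i.se_gp for i in instruments], dtype=float)
    bgd = np.array([i.beta_gd for i in instruments], dtype=float)
    sgd = np.array([i.se_gd for i in instruments], dtype=float)
    return bgp, sgp, bgd, sgd


# ---------------------------------------------------------------- Wald ratio

def wald_ratio(
    inst: HarmonizedInstrument,
    delta_order: int = 1,
) -> CausalEstimate:
    """Per-SNP causal estimate ``theta = beta_gd / beta_gp``.

    The standard error is the delta-method expansion of the ratio:
    first order ``se_gd / |beta_gp|`` (default), or second order adding the
    contribution of the uncertainty in the denominator,
    ``sqrt(se_gd^2/beta_gp^2 + beta_gd^2 * se_gp^2 / beta_gp^4)``.
    """
    if inst.beta_gp == 0:
        raise EstimationError(f"wald_ratio: beta_gp is zero for {inst.rsid}")
    theta = inst.beta_gd / inst.beta_gp
    if delta_order == 1:
        se = inst.se_gd / abs(inst.beta_gp)
    elif delta_order == 2:
        se = np.sqrt(
            inst.se_gd**2 / inst.beta_gp**2
            + inst.beta_gd**2 * inst.se_gp**2 / inst.beta_gp**4
        )
    else:
        raise EstimationError(f"delta_order must be 1 or 2, got {delta_order}")
    return _wald_estimate("wald", theta, se, n_snps=1)


def _ratio_weights(instruments, delta_order=1):
    """Wald ratios and their inverse-variance weights."""
    ratios = np.empty(len(instruments))
    weights = np.empty(len(instruments))
    for k, inst in enumerate(instruments):
        est = wald_ratio(inst, delta_order=delta_order)
        ratios[k] = est.theta
        weights[k] = 1.0 / est.se**2
    return ratios, weights


# ----------------------------------------------------------------------- IVW

def ivw_estimate(
    instruments: Sequence[HarmonizedInstrument],
    delta_order: int = 1,
) -> CausalEstimate:
    """Fixed-effect inverse-variance weighted average of Wald ratios."""
    if not instruments:
        raise EstimationError("ivw_estimate: empty instrument set")
    ratios, weights = _ratio_weights(instruments, delta_order)
    theta = np.sum(weights * ratios) / np.sum(weights)
    se = 1.0 / np.sqrt(np.sum(weights))
    return _wald_estimate("ivw", theta, se, n_snps=len(instruments))


# ---------------------------------------------------------------- likelihood

def _profile_loglik(theta, bgp, sgp, bgd, sgd):
    """Log-likelihood at ``theta`` with the xi_j maximized out.

    For fixed theta the optimal xi_j is a precision-weighted combination of
    the two measurements, and the maximized contribution collapses to the
    residual of beta_gd on theta*beta_gp with variance
    ``se_gd^2 + theta^2 * se_gp^2``.
    """
    return -0.5 * np.sum((bgd - theta * bgp) ** 2 / (sgd**2 + theta**2 * sgp**2))


def likelihood_estimate(
    instruments: Sequence[HarmonizedInstrument],
    ci_method: str = "profile",
    theta_bounds: tuple[float, float] = (-10.0, 10.0),
    xtol: float = 1e-8,
) -> CausalEstimate:
    """Maximum-likelihood causal estimate under the bivariate normal model.

    The per-SNP true exposure effects are profiled out in closed form,
    leaving a one-dimensional maximization over theta (bounded, tolerance
    ``xtol``), which makes the estimator deterministic. Measurement errors
    are independent across SNPs and between the two studies (two-sample
    design, zero overlap).

    ``ci_method="profile"`` inverts the likelihood-ratio test
    (2*delta-loglik = chi2_1(0.95)); ``"wald"`` uses the observed-information
    standard error. Both report the Wald p-value.
    """
    if len(instruments) < 2:
        raise EstimationError("likelihood_estimate: need at least 2 instruments")
    if ci_method not in ("profile", "wald"):
        raise EstimationError(f"unknown ci_method {ci_method!r}")
    bgp, sgp, bgd, sgd = _arrays(instruments)

    res = optimize.minimize_scalar(
        lambda t: -_profile_loglik(t, bgp, sgp, bgd, sgd),
        bounds=theta_bounds,
        method="bounded",
        options={"xatol": xtol},
    )
    if not res.success:
        raise EstimationError(f"likelihood optimizer failed: {res.message}")
    theta_hat = float(res.x)
    ll_max = _profile_loglik(theta_hat, bgp, sgp, bgd, sgd)

    # Observed information from the profile likelihood curvature.
    h = max(1e-5, 1e-5 * abs(theta_hat))
    curv = (
        _profile_loglik(theta_hat + h, bgp, sgp, bgd, sgd)
        - 2 * ll_max
        + _profile_loglik(theta_hat - h, bgp, sgp, bgd, sgd)
    ) / h**2
    if curv >= 0:
        raise EstimationError("likelihood surface not locally concave at optimum")
    se = float(1.0 / np.sqrt(-curv))

    if ci_method == "wald":
        ci_low, ci_high = theta_hat - Z95 * se, theta_hat + Z95 * se
    else:
        ci_low, ci_high = _profile_ci(theta_hat, ll_max, se, bgp, sgp, bgd, sgd,
                                      theta_bounds)

    return CausalEstimate(
        method="likelihood",
        theta=theta_hat,
        se=se,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        pvalue=_wald_pvalue(theta_hat, se),
        n_snps=len(instruments),
    )


def _profile_ci(theta_hat, ll_max, se, bgp, sgp, bgd, sgd, bounds):
    """95% interval where the profile log-likelihood drops by chi2_1(.95)/2."""
    target = ll_max - CHI2_95 / 2.0

    def deficit(t):
        return _profile_loglik(t, bgp, sgp, bgd, sgd) - target

    def solve(direction):
        step = max(se, 1e-6)
        t = theta_hat
        for _ in range(200):
            t_next = t + direction * step
            t_next = float(np.clip(t_next, bounds[0], bounds[1]))
            if deficit(t_next) < 0:
                return optimize.brentq(deficit, min(t, t_next), max(t, t_next),
                                       xtol=1e-10)
            if t_next in bounds:
                raise EstimationError(
                    "profile CI endpoint outside theta bounds; widen theta_bounds"
                )
            t = t_next
            step *= 1.6
        raise EstimationError("profile CI search did not bracket the cutoff")

    return solve(-1.0), solve(+1.0)


# ------------------------------------------------------------ weighted median

def _weighted_median_of_ratios(ratios, weights):
    """Median of the weighted empirical distribution of ordered ratios.

    The j-th order statistic represents the percentile
    ``p_j = cumsum(w)_j - w_j / 2`` of the distribution (weights
    normalized); the median linearly interpolates between adjacent order
    statistics at p = 1/2, returning the boundary ratio below p_1 or above
    p_J. Ties broken by a stable sort on the ratio values.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, r))


def weighted_median_estimate(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 10_000,
    seed: int | None = None,
    delta_order: int = 1,
) -> CausalEstimate:
    """Weighted median of the Wald ratios, robust to <50% invalid weight.

    The point estimate is the 50th percentile of the inverse-variance
    weighted empirical distribution of ordered per-SNP ratio estimates. The
    standard error is a parametric bootstrap: ``n_boot`` replicates resample
    beta_gp and beta_gd from normal distributions centred at the observed
    values with the reported SEs, and the SE is the standard deviation of
    the replicate medians. A ``seed`` makes the bootstrap reproducible.
    """
    if len(instruments) < 3:
        raise EstimationError("weighted_median_estimate: need at least 3 instruments")
    if n_boot < 1:
        raise EstimationError("n_boot must be >= 1")
    bgp, sgp, bgd, sgd = _arrays(instruments)
    ratios, weights = _ratio_weights(instruments, delta_order)

    wmax = np.max(weights) / np.sum(weights)
    if wmax > 1.0 - 1e-12:
        logger.warning("weighted median: all weight on one SNP; returning its ratio")

    theta = _weighted_median_of_ratios(ratios, weights)

    rng = np.random.default_rng(seed)
    boot_bgp = rng.normal(bgp, sgp, size=(n_boot, len(instruments)))
    boot_bgd = rng.normal(bgd, sgd, size=(n_boot, len(instruments)))
    # Weights stay fixed at their observed values across replicates (the
    # standard bootstrap for this estimator); only the ratios are
    # resampled. Degenerate beta_gp draws near zero can blow up single
    # ratios, but the median is robust to them.
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_ratio = boot_bgd / boot_bgp
    boot_theta = _batch_weighted_median(boot_ratio, np.broadcast_to(weights, boot_ratio.shape))
    se = float(np.std(boot_theta, ddof=1)) if n_boot > 1 else 0.0

    return _wald_estimate("weighted_median", theta, se, n_snps=len(instruments))


def _batch_weighted_median(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians (vectorized over bootstrap replicates)."""
    order = np.argsort(ratios, axis=1, kind="stable")
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / np.sum(w, axis=1, keepdims=True)
    p = np.cumsum(w, axis=1) - w / 2.0
    out = np.empty(ratios.shape[0])
    for i in range(ratios.shape[0]):
        out[i] = np.interp(0.5, p[i], r[i])
    return out


# ------------------------------------------------------------------ MR-Egger

def egger_regression(
    instruments: Sequence[HarmonizedInstrument],
) -> EggerResult:
    """Weighted regression of beta_gd on beta_gp with a free intercept.

    Weights are ``1/se_gd**2``. The slope is the pleiotropy-adjusted causal
    estimate; the intercept estimates the average direct (pleiotropic)
    effect of the instruments on the outcome and its two-sided test is the
    directional-pleiotropy test. Inference uses the t distribution with
    J - 2 degrees of freedom and the estimated residual scale, as in an
    ordinary weighted least-squares fit. Requires the instruments to be
    oriented so beta_gp >= 0 (guaranteed by harmonization) — the intercept
    is not invariant to allele reorientation otherwise.
    """
    if len(instruments) < 3:
        raise EstimationError("egger_regression: need at least 3 instruments")
    bgp, sgp, bgd, sgd = _arrays(instruments)
    if np.ptp(bgp) == 0:
        raise EstimationError("egger_regression: all beta_gp identical (collinear design)")

    import statsmodels.api as sm

    X = sm.add_constant(bgp)
    fit = sm.WLS(bgd, X, weights=1.0 / sgd**2).fit()
    intercept, slope = fit.params
    se_int, se_slope = fit.bse
    p_int, p_slope = fit.pvalues
    tcrit = float(stats.t.ppf(0.975, df=len(instruments) - 2))

    slope_est = CausalEstimate(
        method="egger_slope",
        theta=float(slope),
        se=float(se_slope),
        ci_low=float(slope - tcrit * se_slope),
        ci_high=float(slope + tcrit * se_slope),
        pvalue=float(p_slope),
        n_snps=len(instruments),
    )
    return EggerResult(
        slope=slope_est,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_pvalue=float(p_int),
    )


# -------------------------------------------------------------- heterogeneity

def _cochran_q(thetas: np.ndarray, weights: np.ndarray) -> HeterogeneityResult:
    pooled = np.sum(weights * thetas) / np.sum(weights)
    q = float(np.sum(weights * (thetas - pooled) ** 2))
    df = len(thetas) - 1
    pvalue = float(stats.chi2.sf(q, df))
    i_squared = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, pvalue=pvalue, i_squared=i_squared)


def snp_heterogeneity(
    instruments: Sequence[HarmonizedInstrument],
    delta_order: int = 1,
) -> HeterogeneityResult:
    """Cochran's Q / I^2 across the per-SNP Wald-ratio causal estimates."""
    if len(instruments) < 2:
        raise EstimationError("snp_heterogeneity: need at least 2 instruments")
    ratios, weights = _ratio_weights(instruments, delta_order)
    return _cochran_q(ratios, weights)


def strata_heterogeneity(
    estimates: Sequence[CausalEstimate],
) -> HeterogeneityResult:
    """Cochran's Q across stratum-level causal estimates (1/se^2 weights)."""
    if len(estimates) < 2:
        raise EstimationError("strata_heterogeneity: need at least 2 estimates")
    thetas = np.array([e.theta for e in estimates])
    weights = np.array([1.0 / e.se**2 for e in estimates])
    return _cochran_q(thetas, weights)
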