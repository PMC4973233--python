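"""Independent brute-force oracles used to cross-check the estimators.

Each oracle recomputes a quantity by a different route than the library:
exhaustive grid search, explicit normal equations, dense-CDF reading, or
enumeration of allele configurations. They are deliberately slow and
simple.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def ivw_by_wls_origin(bgp, sgd, bgd):
    """IVW as weighted least squares of bgd on bgp through the origin."""
    w = 1.0 / np.asarray(sgd) ** 2
    bgp = np.asarray(bgp)
    bgd = np.asarray(bgd)
    theta = np.sum(w * bgp * bgd) / np.sum(w * bgp**2)
    se = 1.0 / np.sqrt(np.sum(w * bgp**2))
    return theta, se


def likelihood_by_grid(bgp, sgp, bgd, sgd, lo=-2.0, hi=2.0, step=1e-4):
    """Grid-search MLE of theta with explicit per-SNP inner profiling.

    For each theta on the grid, the nuisance xi_j maximizing the two normal
    log-density terms has the closed form of a precision-weighted average;
    the summed log-likelihood is evaluated term by term (a different
    algebraic route than the residual-form profile likelihood).
    """
    bgp, sgp, bgd, sgd = map(np.asarray, (bgp, sgp, bgd, sgd))
    grid = np.arange(lo, hi + step, step)
    best_theta, best_ll = None, -np.inf
    for theta in grid:
        xi = (bgp / sgp**2 + theta * bgd / sgd**2) / (1.0 / sgp**2 + theta**2 / sgd**2)
        ll = float(
            -0.5 * np.sum((bgp - xi) ** 2 / sgp**2)
            - 0.5 * np.sum((bgd - theta * xi) ** 2 / sgd**2)
        )
        if ll > best_ll:
            best_ll, best_theta = ll, float(theta)
    return best_theta


def weighted_median_by_cdf_grid(ratios, weights, n_grid=1_000_000):
    """Median read off a dense evaluation of the weighted empirical CDF.

    The CDF assigns percentile cumsum(w) - w/2 to each ordered ratio and is
    linear in between; the oracle tabulates it on a dense grid and returns
    the first grid point where it reaches 1/2.
    """
    ratios = np.asarray(ratios, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - w / 2.0
    grid = np.linspace(r[0], r[-1], n_grid)
    cdf = np.interp(grid, r, p)
    return float(grid[np.searchsorted(cdf, 0.5)])


def egger_by_normal_equations(bgp, sgd, bgd):
    """Weighted with-intercept regression solved by explicit normal equations."""
    bgp, sgd, bgd = map(np.asarray, (bgp, sgd, bgd))
    w = 1.0 / sgd**2
    X = np.column_stack([np.ones_like(bgp), bgp])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * bgd)
    intercept, slope = np.linalg.solve(A, b)
    return float(intercept), float(slope)


def harmonize_by_enumeration(exp_rec, out_rec, eaf_window=(0.42, 0.58)):
    """Resolve one exposure/outcome pair by enumerating the 4 outcome readings.

    Each reading is (label swap? x strand complement?) applied to the
    outcome record; readings whose allele labels match the exposure pair
    are candidates. For palindromic SNPs two candidates with opposite signs
    remain and are disambiguated by allele-frequency proximity (dropped if
    either study's eaf lies inside the ambiguity window). Returns
    (beta_gd on the exposure-increasing allele, beta_gp oriented >= 0)
    or the string reason for exclusion.
    """
    configs = []
    for swap in (False, True):
        for strand in (False, True):
            ea, oa = out_rec.effect_allele, out_rec.other_allele
            beta, eaf = out_rec.beta, out_rec.eaf
            if swap:
                ea, oa = oa, ea
                beta = -beta
                eaf = None if eaf is None else 1.0 - eaf
            if strand:
                ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
            if (ea, oa) == (exp_rec.effect_allele, exp_rec.other_allele):
                configs.append((beta, eaf))
    if not configs:
        return "irreconcilable"
    distinct_betas = {round(c[0], 12) for c in configs}
    if len(distinct_betas) > 1:  # palindromic ambiguity
        lo, hi = eaf_window
        if exp_rec.eaf is None or any(c[1] is None for c in configs):
            return "palindromic_no_eaf"
        if lo <= exp_rec.eaf <= hi or any(lo <= c[1] <= hi for c in configs):
            return "palindromic_ambiguous"
        beta_gd, _ = min(configs, key=lambda c: abs(c[1] - exp_rec.eaf))
    else:
        beta_gd = configs[0][0]
    beta_gp = exp_rec.beta
    if beta_gp < 0:
        beta_gp, beta_gd = -beta_gp, -beta_gd
    return beta_gp, beta_gd
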