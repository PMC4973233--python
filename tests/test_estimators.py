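import numpy as np
import pytest
from scipy import stats

from twosample_mr import (
    EstimationError,
    egger_regression,
    ivw_estimate,
    likelihood_estimate,
    snp_heterogeneity,
    strata_heterogeneity,
    wald_ratio,
    weighted_median_estimate,
)
from twosample_mr.estimators import _wald_estimate, _weighted_median_of_ratios

from conftest import make_instruments, random_instruments
from _oracles import (
    egger_by_normal_equations,
    ivw_by_wls_origin,
    likelihood_by_grid,
    weighted_median_by_cdf_grid,
)


class TestWaldRatio:
    def test_ratio_and_first_order_se(self):
        (inst,) = make_instruments([0.20], [0.01], [0.10], [0.02])
        est = wald_ratio(inst)
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_numerator_gives_zero(self):
        (inst,) = make_instruments([0.20], [0.01], [0.0], [0.02])
        assert wald_ratio(inst).theta == 0.0

    def test_zero_denominator_names_snp(self):
        (inst,) = make_instruments([0.0], [0.01], [0.1], [0.02], rsids=["rsX"])
        with pytest.raises(EstimationError, match="rsX"):
            wald_ratio(inst)

    def test_second_order_se_matches_monte_carlo(self):
        """Delta-method SE vs the sd of the ratio over 1e6 normal draws."""
        (inst,) = make_instruments([0.20], [0.02], [0.10], [0.02])
        est = wald_ratio(inst, delta_order=2)
        rng = np.random.default_rng(7)
        num = rng.normal(0.10, 0.02, 1_000_000)
        den = rng.normal(0.20, 0.02, 1_000_000)
        mc_sd = np.std(num / den)
        assert est.se == pytest.approx(mc_sd, rel=0.05)


class TestIVW:
    def test_single_snp_equals_wald(self, rng):
        insts = random_instruments(rng, n=1)
        ivw = ivw_estimate(insts)
        wald = wald_ratio(insts[0])
        assert ivw.theta == pytest.approx(wald.theta)
        assert ivw.se == pytest.approx(wald.se)

    def test_equal_weights_is_plain_mean(self):
        insts = make_instruments([0.1, 0.1], [0.01, 0.01], [0.02, 0.04], [0.01, 0.01])
        assert ivw_estimate(insts).theta == pytest.approx(0.3)

    def test_matches_wls_through_origin(self, rng):
        insts = random_instruments(rng, n=10)
        est = ivw_estimate(insts)
        theta, se = ivw_by_wls_origin(
            [i.beta_gp for i in insts], [i.se_gd for i in insts],
            [i.beta_gd for i in insts])
        assert est.theta == pytest.approx(theta, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_empty_set_rejected(self):
        with pytest.raises(EstimationError):
            ivw_estimate([])


class TestLikelihood:
    def test_matches_grid_search_oracle(self, rng):
        insts = make_instruments([0.05, 0.08], [0.01, 0.012], [0.02, 0.05],
                                 [0.02, 0.025])
        est = likelihood_estimate(insts)
        grid_theta = likelihood_by_grid(
            [i.beta_gp for i in insts], [i.se_gp for i in insts],
            [i.beta_gd for i in insts], [i.se_gd for i in insts])
        assert est.theta == pytest.approx(grid_theta, abs=1e-4)

    def test_no_measurement_error_limit_equals_ivw(self, rng):
        insts = random_instruments(rng, n=8)
        for inst in insts:
            inst.se_gp = 1e-8
        lik = likelihood_estimate(insts)
        ivw = ivw_estimate(insts)
        assert lik.theta == pytest.approx(ivw.theta, abs=1e-4)

    def test_profile_ci_brackets_estimate_and_matches_wald_in_precision_limit(self, rng):
        insts = random_instruments(rng, n=40)
        for inst in insts:  # high-precision limit
            inst.se_gp = 1e-7
            inst.se_gd = 1e-4
            inst.beta_gd = 0.3 * inst.beta_gp
        prof = likelihood_estimate(insts, ci_method="profile")
        wald = likelihood_estimate(insts, ci_method="wald")
        assert prof.ci_low < prof.theta < prof.ci_high
        assert prof.ci_low == pytest.approx(wald.ci_low, abs=1e-3)
        assert prof.ci_high == pytest.approx(wald.ci_high, abs=1e-3)

    def test_needs_two_instruments(self, rng):
        with pytest.raises(EstimationError):
            likelihood_estimate(random_instruments(rng, n=1))


class TestWeightedMedian:
    def test_symmetric_three_ratio_set(self):
        # ratios {0.4, 0.5, 0.6} with normalized weights {0.25, 0.5, 0.25}
        assert _weighted_median_of_ratios(
            np.array([0.4, 0.5, 0.6]), np.array([0.25, 0.5, 0.25])
        ) == pytest.approx(0.5)

    def test_identical_ratios_degenerate(self):
        insts = make_instruments([0.1, 0.2, 0.4], [0.01] * 3,
                                 [0.03, 0.06, 0.12], [0.001] * 3)
        est = weighted_median_estimate(insts, n_boot=500, seed=1)
        assert est.theta == pytest.approx(0.3)
        assert est.se < 0.05

    def test_matches_cdf_grid_oracle(self, rng):
        insts = random_instruments(rng, n=7)
        est = weighted_median_estimate(insts, n_boot=1, seed=0)
        ratios = np.array([i.beta_gd / i.beta_gp for i in insts])
        weights = np.array([(i.beta_gp / i.se_gd) ** 2 for i in insts])
        oracle = weighted_median_by_cdf_grid(ratios, weights)
        assert est.theta == pytest.approx(oracle, abs=1e-4)

    def test_bootstrap_seeded_and_reproducible(self, rng):
        insts = random_instruments(rng, n=10)
        a = weighted_median_estimate(insts, n_boot=200, seed=42)
        b = weighted_median_estimate(insts, n_boot=200, seed=42)
        c = weighted_median_estimate(insts, n_boot=200, seed=43)
        assert a.se == b.se
        assert a.se != c.se

    def test_needs_three_instruments(self, rng):
        with pytest.raises(EstimationError):
            weighted_median_estimate(random_instruments(rng, n=2), n_boot=10, seed=0)


class TestEgger:
    def test_exact_line_recovered(self):
        bgp = np.array([0.02, 0.04, 0.06, 0.08])
        bgd = 0.05 + 1.2 * bgp
        insts = make_instruments(bgp, [0.01] * 4, bgd, [0.02] * 4)
        res = egger_regression(insts)
        assert res.intercept == pytest.approx(0.05, abs=1e-12)
        assert res.slope.theta == pytest.approx(1.2, abs=1e-12)

    def test_no_pleiotropy_null_has_zero_intercept(self):
        bgp = np.array([0.02, 0.05, 0.07, 0.033, 0.061])
        insts = make_instruments(bgp, [0.01] * 5, 0.3 * bgp, [0.02] * 5)
        res = egger_regression(insts)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope.theta == pytest.approx(0.3, abs=1e-10)

    def test_matches_normal_equations(self, rng):
        insts = random_instruments(rng, n=20)
        res = egger_regression(insts)
        intercept, slope = egger_by_normal_equations(
            [i.beta_gp for i in insts], [i.se_gd for i in insts],
            [i.beta_gd for i in insts])
        assert res.intercept == pytest.approx(intercept, abs=1e-8)
        assert res.slope.theta == pytest.approx(slope, abs=1e-8)

    def test_intercept_pvalue_uniform_under_null(self):
        """No pleiotropy: the directional-pleiotropy test should be
        calibrated, i.e. its p-value uniform over replicates (KS, alpha 0.01)."""
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(500):
            bgp = rng.uniform(0.01, 0.05, 25)
            sgd = rng.uniform(0.01, 0.03, 25)
            bgd = 0.3 * bgp + rng.normal(0, sgd)
            insts = make_instruments(bgp, np.full(25, 1e-4), bgd, sgd)
            pvals.append(egger_regression(insts).intercept_pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_collinear_design_rejected(self):
        insts = make_instruments([0.05] * 4, [0.01] * 4, [0.02] * 4, [0.02] * 4)
        with pytest.raises(EstimationError, match="collinear"):
            egger_regression(insts)


class TestHeterogeneity:
    def test_identical_ratios_no_heterogeneity(self):
        bgp = np.array([0.1, 0.2, 0.4])
        insts = make_instruments(bgp, [0.01] * 3, 0.5 * bgp, [0.02] * 3)
        het = snp_heterogeneity(insts)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.i_squared == 0.0

    def test_q_at_chi_square_quantile_gives_p_05(self):
        # J=2: Q = (t1-t2)^2/(v1+v2); build t2 so Q hits chi2_1(0.95)
        q95 = stats.chi2.ppf(0.95, 1)
        se1 = se2 = 0.1
        delta = np.sqrt(q95 * (se1**2 + se2**2))
        insts = make_instruments([0.1, 0.1], [1e-8, 1e-8],
                                 [0.0, delta * 0.1], [se1 * 0.1, se2 * 0.1])
        het = snp_heterogeneity(insts)
        assert het.pvalue == pytest.approx(0.05, abs=1e-10)
        assert het.i_squared == pytest.approx((1 - 1 / q95) * 100)

    def test_permutation_invariance(self, rng):
        insts = random_instruments(rng, n=12)
        q1 = snp_heterogeneity(insts).q
        perm = [insts[i] for i in rng.permutation(12)]
        assert snp_heterogeneity(perm).q == pytest.approx(q1, rel=1e-12)

    def test_strata_identical_estimates(self):
        ests = [_wald_estimate("likelihood", 0.3, 0.1, 10) for _ in range(3)]
        het = strata_heterogeneity(ests)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.pvalue == pytest.approx(1.0)

    def test_two_strata_z_identity(self):
        # |t1-t2| / sqrt(se1^2+se2^2) = 1.96  =>  p ~ 0.05
        se1, se2 = 0.1, 0.15
        delta = 1.96 * np.sqrt(se1**2 + se2**2)
        ests = [_wald_estimate("likelihood", 0.0, se1, 10),
                _wald_estimate("likelihood", delta, se2, 10)]
        assert strata_heterogeneity(ests).pvalue == pytest.approx(0.05, abs=5e-4)

    def test_three_strata_matches_direct_q(self, rng):
        thetas = rng.normal(0, 0.3, 3)
        ses = rng.uniform(0.05, 0.2, 3)
        ests = [_wald_estimate("likelihood", t, s, 10) for t, s in zip(thetas, ses)]
        w = 1 / ses**2
        pooled = np.sum(w * thetas) / np.sum(w)
        q = np.sum(w * (thetas - pooled) ** 2)
        assert strata_heterogeneity(ests).q == pytest.approx(q, rel=1e-12)


@pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
def test_scale_equivariance_of_all_estimators(rng, c):
    """Rescaling the exposure units by c rescales every theta-hat by 1/c."""
    insts = random_instruments(rng, n=12)
    scaled = make_instruments(
        [i.beta_gp * c for i in insts], [i.se_gp * c for i in insts],
        [i.beta_gd for i in insts], [i.se_gd for i in insts])
    for fit in (ivw_estimate,
                likelihood_estimate,
                lambda x: weighted_median_estimate(x, n_boot=1, seed=0),
                lambda x: egger_regression(x).slope):
        theta = fit(insts).theta
        theta_scaled = fit(scaled).theta
        assert theta_scaled == pytest.approx(theta / c, rel=1e-5)
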