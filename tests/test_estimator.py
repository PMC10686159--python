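"""Conditional exceedance rates, convergence in k, up-crossing check,
nonstationary mixture."""

import numpy as np
import pytest
from scipy import stats

from mdof_extremes import (
    MixtureSpec,
    SimulationConfig,
    check_k_convergence,
    estimate_pk,
    mean_upcrossing_rate,
    mixture_longterm,
    nonexceedance_probability,
    panel_to_merged,
    simulate_panel,
    system_failure_probability,
    upcrossing_nonexceedance,
)
from mdof_extremes.core import ExceedanceCurve

from conftest import brute_force_pk, merged_from_values


class TestEstimatePk:
    def test_worked_example_k1(self):
        mv = merged_from_values([0.2, 0.5, 0.9, 0.4])
        c = estimate_pk(mv, np.array([0.6]), k=1)
        assert (c.n_cond[0], c.n_exc[0]) == (4, 1)
        assert c.p[0] == pytest.approx(0.25)

    def test_worked_example_k2(self):
        # eligible j with R_{j-1} <= 0.6: j=2 (no exceed), j=3 (0.9 > 0.6
        # exceeds), j=4 ineligible since R_3 = 0.9 > 0.6
        mv = merged_from_values([0.2, 0.5, 0.9, 0.4])
        c = estimate_pk(mv, np.array([0.6]), k=2)
        assert (c.n_cond[0], c.n_exc[0]) == (2, 1)
        assert c.p[0] == pytest.approx(0.5)

    def test_nothing_exceeds_design_limit(self):
        mv = merged_from_values([0.2, 0.5, 0.9, 0.4])
        for k in (1, 2, 3):
            assert estimate_pk(mv, np.array([1.0]), k=k).p[0] == 0.0

    def test_tie_at_scaled_limit_is_nonexceedance(self):
        mv = merged_from_values([0.6, 0.9])
        c = estimate_pk(mv, np.array([0.6]), k=2)
        # R_1 = 0.6 <= 0.6 satisfies the conditioning bound (non-strict)
        assert c.n_cond[0] == 1 and c.n_exc[0] == 1

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_matches_brute_force(self, k):
        rng = np.random.default_rng(123)
        values = rng.uniform(size=400)
        limits = rng.uniform(0.5, 1.5, size=400)
        mv = merged_from_values(values, limits=limits)
        lams = np.array([0.3, 0.55, 0.8, 1.0])
        curve = estimate_pk(mv, lams, k=k)
        for i, lam in enumerate(lams):
            p, nc, ne = brute_force_pk(values, limits, lam, k)
            assert (curve.n_cond[i], curve.n_exc[i]) == (nc, ne)
            assert curve.p[i] == pytest.approx(p)

    def test_unsupported_points_flagged(self):
        mv = merged_from_values([0.9, 0.9, 0.9])
        c = estimate_pk(mv, np.array([0.5]), k=2)  # conditioning never holds
        assert c.n_cond[0] == 0 and c.p[0] == 0.0
        assert not c.supported[0]

    def test_k_larger_than_N_is_error(self):
        mv = merged_from_values([0.2, 0.5])
        with pytest.raises(ValueError):
            estimate_pk(mv, np.array([0.5]), k=3)

    def test_empty_grid_is_error(self):
        mv = merged_from_values([0.2, 0.5])
        with pytest.raises(ValueError):
            estimate_pk(mv, np.array([]), k=1)

    def test_lambda_above_one_warns(self):
        mv = merged_from_values([0.2, 0.5])
        with pytest.warns(UserWarning, match="design limit"):
            estimate_pk(mv, np.array([1.2]), k=1)


class TestNonexceedance:
    def test_zero_rate_gives_certainty(self):
        c = ExceedanceCurve(1, [0.5], [0.0], [10], [0], N=100)
        assert nonexceedance_probability(c)[0] == 1.0

    def test_closed_form(self):
        c = ExceedanceCurve(1, [0.5], [0.01], [100], [1], N=100)
        assert nonexceedance_probability(c)[0] == pytest.approx(np.exp(-1.0))

    def test_failure_probability_requires_lambda_one(self):
        c = ExceedanceCurve(1, [0.5], [0.01], [100], [1], N=100)
        with pytest.raises(ValueError):
            system_failure_probability(c)
        c1 = ExceedanceCurve(1, [0.5, 1.0], [0.01, 0.0], [100, 100], [1, 0], N=100)
        assert system_failure_probability(c1) == 0.0

    def test_matches_direct_empirical_frequency_iid(self):
        # for iid uniforms P_1(lam) ~ exp(-N p) should track the empirical
        # frequency of {all R_j <= lam} where N*p is of order one
        rng = np.random.default_rng(21)
        N, lam, reps = 100, 0.99, 2000
        u = rng.uniform(size=(reps, N))
        direct = np.mean(np.all(u <= lam, axis=1))
        ps = np.count_nonzero(u > lam, axis=1) / N
        approx = np.exp(-N * np.mean(ps))
        se = np.sqrt(direct * (1 - direct) / reps)
        assert abs(approx - direct) < 3 * se + abs(lam**N - np.exp(-N * (1 - lam)))


class TestKConvergence:
    def _curve(self, k, p):
        n = len(p)
        return ExceedanceCurve(
            k, np.linspace(0.5, 1.0, n), p, np.full(n, 100), np.full(n, 1), N=1000
        )

    def test_identical_curves_converge_at_first_comparable_level(self):
        p = [0.2, 0.1, 0.05]
        result = check_k_convergence([self._curve(2, p), self._curve(3, p)])
        assert result.k_star == 3 and result.converged
        assert result.discrepancy[3] == 0.0

    def test_memoryless_data_converges_at_k2(self):
        panel = simulate_panel(
            SimulationConfig(
                n_components=2, n_years=5000, lag1_autocorr=0.0, cross_corr=0.0, seed=7
            )
        )
        merged = panel_to_merged(panel, mode="all_samples")
        from mdof_extremes import estimate_curves

        curves = estimate_curves(merged, k_max=3)
        result = check_k_convergence(curves)
        assert result.k_star == 2 and result.converged

    def test_single_curve_is_error(self):
        with pytest.raises(ValueError):
            check_k_convergence([self._curve(1, [0.1, 0.05, 0.02])])

    def test_mismatched_grids_are_error(self):
        a = self._curve(1, [0.1, 0.05, 0.02])
        b = ExceedanceCurve(2, [0.1, 0.2, 0.3], [0.1, 0.05, 0.02], [9, 9, 9], [1, 1, 1], N=10)
        with pytest.raises(ValueError):
            check_k_convergence([a, b])

    def test_unconverged_flagged(self):
        a = self._curve(1, [0.4, 0.3, 0.2])
        b = self._curve(2, [0.1, 0.05, 0.02])
        result = check_k_convergence([a, b], tol=0.05)
        assert result.k_star == 2 and not result.converged


class TestUpcrossing:
    def test_direct_count(self):
        assert mean_upcrossing_rate([0, 1, 0, 1, 0], 0.5, 4.0) == pytest.approx(0.5)

    def test_constant_series_never_crosses(self):
        assert mean_upcrossing_rate([0.3] * 10, 0.5, 9.0) == 0.0

    def test_nonpositive_duration_is_error(self):
        with pytest.raises(ValueError):
            mean_upcrossing_rate([0, 1], 0.5, 0.0)

    def test_ar1_rate_matches_bivariate_normal_orthant(self):
        # discrete-time crossing rate of a standard-Gaussian AR(1):
        # Prob{x_t <= level < x_{t+1}} from the bivariate normal orthant
        rho, level, T = 0.5, 1.0, 200_000
        rng = np.random.default_rng(9)
        eps = rng.standard_normal(T)
        x = np.empty(T)
        x[0] = eps[0]
        scale = np.sqrt(1 - rho**2)
        for t in range(1, T):
            x[t] = rho * x[t - 1] + scale * eps[t]
        nu = mean_upcrossing_rate(x, level, T - 1)
        mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        p_cross = stats.norm.cdf(level) - mvn.cdf([level, level])
        se = np.sqrt(p_cross * (1 - p_cross) / (T - 1))
        assert abs(nu - p_cross) < 3 * se

    def test_k1_upcrossing_consistency(self):
        # exp(-N p_1(lam)) and exp(-nu+ T) agree for a single component in
        # all_samples mode up to the clustering term N p^2
        rng = np.random.default_rng(17)
        values = rng.uniform(size=2000)
        mv = merged_from_values(values)
        lam = 0.995
        p1 = estimate_pk(mv, np.array([lam]), 1).p[0]
        nu = mean_upcrossing_rate(values, lam, float(len(values)))
        lhs = np.log(upcrossing_nonexceedance(nu, float(len(values))))
        rhs = -len(values) * p1
        # the two exponents are event counts; they differ only by clustered
        # or boundary exceedances, a handful of events at most here
        assert abs(lhs - rhs) <= 4.0
        assert -rhs == pytest.approx(len(values) * (1 - lam), rel=0.5)


class TestMixture:
    def _curve(self, p, k=2):
        n = len(p)
        return ExceedanceCurve(
            k, np.linspace(0.5, 1.0, n), p, np.full(n, 50), np.full(n, 1), N=500
        )

    def test_single_state_identity(self):
        c = self._curve([0.3, 0.2, 0.1])
        out = mixture_longterm(MixtureSpec(weights=[1.0], curves=(c,)))
        np.testing.assert_allclose(out.p, c.p)
        assert out.k == c.k

    def test_identical_states_any_weights(self):
        c = self._curve([0.3, 0.2, 0.1])
        out = mixture_longterm(MixtureSpec(weights=[0.3, 0.7], curves=(c, c)))
        np.testing.assert_allclose(out.p, c.p)

    def test_weighted_sum(self):
        a = self._curve([0.1, 0.1, 0.1])
        b = self._curve([0.3, 0.3, 0.3])
        out = mixture_longterm(MixtureSpec(weights=[0.25, 0.75], curves=(a, b)))
        np.testing.assert_allclose(out.p, 0.25 * 0.1 + 0.75 * 0.3)

    def test_counts_not_meaningful_after_mixing(self):
        a = self._curve([0.1, 0.1, 0.1])
        out = mixture_longterm(MixtureSpec(weights=[1.0], curves=(a,)))
        assert not out.has_counts

    def test_bad_weights_rejected(self):
        a = self._curve([0.1, 0.1, 0.1])
        with pytest.raises(ValueError):
            MixtureSpec(weights=[0.5, 0.6], curves=(a, a))
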