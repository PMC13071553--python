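"""Selection-event geometry, truncated-normal inference, conditional MLE."""

import numpy as np
import pytest
from scipy import integrate, stats

from refinemap.estimators import marginal_coefficients
from refinemap.inference import finemap_region
from refinemap.psat import (
    SelectionSpec,
    TruncationRegion,
    conditional_mle,
    conditioning_decomposition,
    make_selection,
    marginal_screen_threshold,
    psat_ci,
    psat_finemap,
    psat_pvalue,
    selection_probability,
    selection_statistic,
    truncation_region,
    truncnorm_cdf,
)

FULL_LINE = TruncationRegion([(-np.inf, np.inf)])


class TestSelectionStatistic:
    def test_equals_squared_marginal_coefficient(self, small_panel, rng):
        y = rng.standard_normal(small_panel.n)
        y = (y - y.mean()) / y.std()
        marg = marginal_coefficients(small_panel, y)
        beta_mc = np.linalg.solve(small_panel.corr, marg.beta_om)
        for j in range(small_panel.p):
            s = selection_statistic(beta_mc, small_panel.corr, j)
            assert s == pytest.approx(marg.beta_om[j] ** 2, abs=1e-12)

    def test_zero_beta_gives_zero(self):
        assert selection_statistic(np.zeros(3), np.eye(3), 1) == 0.0

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            selection_statistic(np.zeros(3), np.eye(3), 3)


class TestScreenThreshold:
    def test_bonferroni_quantile_value(self):
        t = marginal_screen_threshold(10_000, 20_000, 0.05)
        z = stats.norm.ppf(1 - 0.05 / 20_000)
        assert z == pytest.approx(4.5648, abs=1e-4)
        assert t == pytest.approx((z / 100.0) ** 2, rel=1e-12)

    def test_degenerate_level_gives_zero(self):
        assert marginal_screen_threshold(100, 1, 0.5) == 0.0

    def test_monotonicity(self):
        base = marginal_screen_threshold(10_000, 20_000)
        assert marginal_screen_threshold(40_000, 20_000) < base
        assert marginal_screen_threshold(10_000, 200_000) > base


class TestConditioningDecomposition:
    def test_identity_sigma_unit_contrast(self):
        beta = np.array([1.0, 2.0, 3.0])
        d = conditioning_decomposition(beta, np.eye(3), np.eye(3)[0])
        assert np.allclose(d.c_vec, [1.0, 0.0, 0.0])
        assert np.allclose(d.w, [0.0, 2.0, 3.0])
        assert d.u_obs == 1.0

    def test_reconstruction_identity_random_contrasts(self, rng):
        from conftest import random_psd

        p = 5
        sig = random_psd(p, rng)
        beta = rng.normal(size=p)
        for _ in range(10):
            eta = rng.normal(size=p)
            d = conditioning_decomposition(beta, sig, eta)
            assert np.allclose(d.w + d.c_vec * d.u_obs, beta, atol=1e-10)

    def test_zero_variance_contrast_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            conditioning_decomposition(np.ones(2), np.zeros((2, 2)), np.ones(2))


class TestTruncationRegion:
    @staticmethod
    def _decomp(u_obs, c_dot_v=1.0, w_dot_v=0.0, p=2):
        # minimal stand-in with the fields truncation_region reads
        from refinemap.psat import ConditioningDecomposition

        return ConditioningDecomposition(
            eta=np.eye(p)[0],
            c_vec=np.array([c_dot_v] + [0.0] * (p - 1)),
            w=np.array([w_dot_v] + [0.0] * (p - 1)),
            u_obs=u_obs,
            var_u=1.0,
        )

    def test_two_rays_a_positive(self):
        sel = SelectionSpec(0, 1.0, np.array([1.0, 0.0]))
        reg = truncation_region(self._decomp(u_obs=2.0), sel)
        assert reg.intervals == [(-np.inf, -1.0), (1.0, np.inf)]

    def test_threshold_zero_gives_punctured_line(self):
        sel = SelectionSpec(0, 0.0, np.array([1.0, 0.0]))
        reg = truncation_region(self._decomp(u_obs=0.5), sel)
        assert reg.intervals == [(-np.inf, 0.0), (0.0, np.inf)]

    def test_a_zero_b_large_gives_full_line(self):
        sel = SelectionSpec(0, 1.0, np.array([0.0, 1.0]))
        d = self._decomp(u_obs=0.3, c_dot_v=0.0)
        d.w = np.array([0.0, 2.0])  # v'w = 2, 4 > t
        reg = truncation_region(d, sel)
        assert reg.is_full_line

    def test_impossible_selection_raises(self):
        sel = SelectionSpec(0, 1.0, np.array([0.0, 1.0]))
        d = self._decomp(u_obs=0.3, c_dot_v=0.0)  # v'w = 0, 0 < t
        with pytest.raises(ValueError, match="impossible|inconsistent"):
            truncation_region(d, sel)

    def test_observation_outside_region_raises(self):
        sel = SelectionSpec(0, 1.0, np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="selection"):
            truncation_region(self._decomp(u_obs=0.5), sel)


class TestTruncnormCdf:
    def test_full_line_is_normal_cdf(self):
        for u in (-1.3, 0.0, 2.2):
            assert truncnorm_cdf(u, 0.0, 1.0, FULL_LINE) == pytest.approx(
                stats.norm.cdf(u), abs=1e-12
            )

    def test_symmetric_two_ray_midpoint(self):
        reg = TruncationRegion([(-np.inf, -1.0), (1.0, np.inf)])
        assert truncnorm_cdf(1.0, 0.0, 1.0, reg) == pytest.approx(0.5, abs=1e-12)

    def test_boundary_values(self):
        reg = TruncationRegion([(0.0, 1.0)])
        assert truncnorm_cdf(-0.5, 0.0, 1.0, reg) == 0.0
        assert truncnorm_cdf(1.5, 0.0, 1.0, reg) == 1.0

    @pytest.mark.parametrize("mu,var", [(0.0, 1.0), (0.7, 0.25), (-2.0, 4.0)])
    def test_agrees_with_numerical_integration(self, mu, var):
        reg = TruncationRegion([(-np.inf, -0.8), (0.5, 1.7), (2.5, np.inf)])
        sd = np.sqrt(var)

        def dens(x):
            return stats.norm.pdf(x, mu, sd)

        total = sum(
            integrate.quad(dens, max(lo, mu - 12 * sd), min(hi, mu + 12 * sd))[0]
            for lo, hi in reg.intervals
        )
        for u in (-1.0, 0.6, 1.0, 3.0):
            below = sum(
                integrate.quad(
                    dens, max(lo, mu - 12 * sd), min(min(hi, u), mu + 12 * sd)
                )[0]
                for lo, hi in reg.intervals
                if lo < u
            )
            assert truncnorm_cdf(u, mu, var, reg) == pytest.approx(
                below / total, abs=1e-8
            )

    def test_deep_tail_truncation_does_not_underflow(self):
        reg = TruncationRegion([(10.0, np.inf)])
        f = truncnorm_cdf(10.5, 0.0, 1.0, reg)
        assert 0.0 < f < 1.0

    def test_monotone_decreasing_in_mu(self):
        reg = TruncationRegion([(-np.inf, -1.0), (1.0, np.inf)])
        vals = [truncnorm_cdf(1.2, mu, 1.0, reg) for mu in (-1.0, 0.0, 1.0, 2.0)]
        assert np.all(np.diff(vals) < 0)


class TestPsatPvalue:
    def test_no_truncation_equals_unadjusted(self):
        from refinemap.psat import ConditioningDecomposition

        d = ConditioningDecomposition(
            eta=np.eye(2)[0], c_vec=np.zeros(2), w=np.zeros(2),
            u_obs=1.5, var_u=0.25,
        )
        p = psat_pvalue(d, FULL_LINE)
        assert p == pytest.approx(2 * stats.norm.sf(1.5 / 0.5), abs=1e-12)

    def test_inner_boundary_gives_p_one(self):
        from refinemap.psat import ConditioningDecomposition

        d = ConditioningDecomposition(
            eta=np.eye(2)[0], c_vec=np.zeros(2), w=np.zeros(2),
            u_obs=1.0, var_u=1.0,
        )
        reg = TruncationRegion([(-np.inf, -1.0), (1.0, np.inf)])
        assert psat_pvalue(d, reg) == pytest.approx(1.0, abs=1e-12)

    def test_null_pvalues_uniform_under_active_selection(self, rng):
        """The truncated-normal pivot: p-values for a null coordinate are
        U(0,1) across selected replicates (KS at 1%)."""
        p = 4
        corr = 0.6 ** np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
        sig = 0.01 * np.linalg.inv(corr)
        beta = np.array([0.08, 0.0, 0.0, 0.0])  # coordinate 1 is null
        sel = SelectionSpec(0, 0.015, corr[:, 0])
        chol = np.linalg.cholesky(sig)
        pvals = []
        while len(pvals) < 2000:
            b = beta + chol @ rng.standard_normal(p)
            if (sel.v @ b) ** 2 > sel.threshold_t:
                d = conditioning_decomposition(b, sig, np.eye(p)[1])
                reg = truncation_region(d, sel)
                pvals.append(psat_pvalue(d, reg))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestSelectionProbability:
    def test_threshold_zero_gives_one(self):
        sel = SelectionSpec(0, 0.0, np.array([1.0, 0.0]))
        assert selection_probability(np.zeros(2), np.eye(2), sel) == 1.0

    def test_null_mean_two_tail_formula(self):
        sel = SelectionSpec(0, 4.0, np.array([1.0, 0.0]))
        got = selection_probability(np.zeros(2), np.eye(2), sel)
        assert got == pytest.approx(2 * stats.norm.sf(2.0), rel=1e-10)

    def test_matches_monte_carlo(self, rng):
        p = 3
        corr = np.array([[1, 0.5, 0.2], [0.5, 1, 0.5], [0.2, 0.5, 1.0]])
        sig = 0.05 * corr
        beta = np.array([0.2, -0.1, 0.0])
        sel = SelectionSpec(1, 0.09, corr[:, 1])
        analytic = selection_probability(beta, sig, sel)
        chol = np.linalg.cholesky(sig)
        draws = beta + (chol @ rng.standard_normal((p, 40_000))).T
        mc = np.mean((draws @ sel.v) ** 2 > sel.threshold_t)
        se = np.sqrt(analytic * (1 - analytic) / 40_000)
        assert abs(analytic - mc) < 3 * se + 1e-4


class TestConditionalMle:
    def test_threshold_zero_returns_input(self):
        sel = SelectionSpec(0, 0.0, np.array([1.0, 0.0]))
        b = np.array([0.4, -0.2])
        assert np.array_equal(conditional_mle(b, 0.01 * np.eye(2), sel), b)

    def test_near_certain_selection_leaves_estimate_unchanged(self):
        sel = SelectionSpec(0, 1e-6, np.array([1.0, 0.0]))
        b = np.array([0.5, 0.1])  # |v'b| >> sqrt(t)
        out = conditional_mle(b, 0.001 * np.eye(2), sel)
        assert np.allclose(out, b, atol=1e-4)

    def test_reduces_post_selection_bias(self, rng):
        """Across selected replicates the conditional MLE is less biased than
        the raw estimate on the screened coordinate."""
        p = 3
        corr = 0.5 ** np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
        sig = 0.02 * np.linalg.inv(corr)
        beta = np.array([0.05, 0.0, 0.0])
        sel = SelectionSpec(0, 0.04, corr[:, 0])
        chol = np.linalg.cholesky(sig)
        raw, mle = [], []
        while len(raw) < 500:
            b = beta + chol @ rng.standard_normal(p)
            if (sel.v @ b) ** 2 > sel.threshold_t:
                raw.append(b)
                mle.append(conditional_mle(b, sig, sel))
        bias_raw = abs(np.mean([b[0] for b in raw]) - beta[0])
        bias_mle = abs(np.mean([b[0] for b in mle]) - beta[0])
        assert bias_mle < bias_raw


class TestPsatCi:
    def test_no_truncation_reduces_to_wald(self):
        from refinemap.psat import ConditioningDecomposition

        d = ConditioningDecomposition(
            eta=np.eye(2)[0], c_vec=np.zeros(2), w=np.zeros(2),
            u_obs=0.3, var_u=0.04,
        )
        lo, hi = psat_ci(d, FULL_LINE, 0.95)
        assert lo == pytest.approx(0.3 - 1.959964 * 0.2, abs=1e-5)
        assert hi == pytest.approx(0.3 + 1.959964 * 0.2, abs=1e-5)

    def test_coverage_under_selection(self, rng):
        p = 2
        sig = 0.04 * np.eye(p)
        beta = np.array([0.15, 0.0])
        sel = SelectionSpec(0, 0.04, np.eye(p)[0])
        chol = np.linalg.cholesky(sig)
        cover, n = 0, 0
        while n < 400:
            b = beta + chol @ rng.standard_normal(p)
            if (sel.v @ b) ** 2 > sel.threshold_t:
                d = conditioning_decomposition(b, sig, np.eye(p)[0])
                reg = truncation_region(d, sel)
                lo, hi = psat_ci(d, reg, 0.95)
                cover += lo <= beta[0] <= hi
                n += 1
        assert abs(cover / n - 0.95) < 2 * np.sqrt(0.95 * 0.05 / n) + 0.01


class TestPsatFinemap:
    def _sim_region(self, rng, n_o=3000, n_r=800, p=6, rho=0.6):
        from refinemap.simulate import (
            ar1_covariance,
            sample_gaussian_panel,
            standardize,
        )

        xo = standardize(sample_gaussian_panel(n_o, ar1_covariance(p, rho), rng))
        xr = standardize(sample_gaussian_panel(n_r, ar1_covariance(p, rho), rng))
        beta = np.zeros(p)
        beta[0] = 0.6
        y = xo.x @ beta + rng.standard_normal(n_o) * 2.0
        y = (y - y.mean()) / y.std()
        return marginal_coefficients(xo, y), xr

    def test_threshold_zero_matches_unadjusted_pipeline(self, rng):
        marg, xr = self._sim_region(rng)
        sel = make_selection(xr, 2, 0.0)
        adj = psat_finemap(marg, xr, sel, method="corrected_empirical")
        unadj = finemap_region(marg, xr, method="corrected_empirical")
        assert np.allclose(adj.p_values, unadj.p_values, atol=1e-9)
        assert np.array_equal(adj.rejected, unadj.rejected)

    def test_refuses_unselected_region(self, rng):
        marg, xr = self._sim_region(rng)
        sel = make_selection(xr, 2, 1e6)
        with pytest.raises(ValueError, match="selection event not satisfied"):
            psat_finemap(marg, xr, sel)
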