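import numpy as np
import pytest

from hetsim import fit_ols, hc_covariance, hc_inference
from hetsim.robust_se import ExactLeverageError


def brute_force_sandwich(X, residuals, h, exponent):
    """Element-wise triple product oracle, no shared code with the module."""
    xtx_inv = np.linalg.inv(X.T @ X)
    w = residuals**2 / (1.0 - h) ** exponent
    meat = sum(w[i] * np.outer(X[i], X[i]) for i in range(len(w)))
    return xtx_inv @ meat @ xtx_inv


class TestSandwichCovariance:
    @pytest.mark.parametrize("estimator", ["HC3", "HC4"])
    def test_matches_brute_force_triple_product(self, estimator, small_fit):
        cov = hc_covariance(small_fit, estimator)
        if estimator == "HC3":
            expo = 2.0
        else:
            expo = np.minimum(4.0, small_fit.n * small_fit.leverage / small_fit.p)
        expected = brute_force_sandwich(
            small_fit.X, small_fit.residuals, small_fit.leverage, expo
        )
        np.testing.assert_allclose(cov.cov, expected, rtol=1e-10)
        np.testing.assert_allclose(cov.cov, cov.cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov.cov) > -1e-12)

    def test_hc3_matches_statsmodels(self, two_pred_fit):
        sm = pytest.importorskip("statsmodels.api")
        res = sm.OLS(two_pred_fit.y, two_pred_fit.X).fit(cov_type="HC3")
        cov = hc_covariance(two_pred_fit, "HC3")
        np.testing.assert_allclose(cov.cov, res.cov_params(), rtol=1e-8)

    def test_balanced_design_delta_is_one(self):
        # 2^2 factorial with +-1 coding: all leverages equal p/n -> delta = 1
        X = np.array(
            [[1, -1, -1], [1, -1, 1], [1, 1, -1], [1, 1, 1]], dtype=float
        )
        fit = fit_ols(X, np.array([0.1, 0.9, 2.1, 2.9]))
        cov = hc_covariance(fit, "HC4")
        np.testing.assert_allclose(fit.leverage, fit.p / fit.n)
        np.testing.assert_allclose(cov.delta, 1.0)

    def test_delta_caps_at_four(self, rng):
        x = np.r_[rng.standard_normal(20), 50.0]  # one extreme-leverage case
        X = np.column_stack([np.ones(21), x])
        fit = fit_ols(X, rng.standard_normal(21))
        cov = hc_covariance(fit, "HC4")
        i = np.argmax(fit.leverage)
        assert fit.n * fit.leverage[i] / fit.p > 4
        assert cov.delta[i] == 4.0
        assert np.all(cov.delta <= 4.0)

    def test_intercept_only_closed_form(self, rng):
        n = 9
        y = rng.standard_normal(n)
        fit = fit_ols(np.ones((n, 1)), y)
        cov = hc_covariance(fit, "HC3")
        r = fit.residuals
        expected = np.sum(r**2) / (n**2 * (1 - 1 / n) ** 2)
        assert cov.cov[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_hc4_uses_per_case_exponent(self):
        # equal-leverage design: n h / p = 1 everywhere, so HC4 must equal
        # the exponent-1 sandwich exactly (and differ from HC3's exponent 2)
        X = np.array([[1, -1], [1, -1], [1, 1], [1, 1]], dtype=float)
        fit = fit_ols(X, np.array([0.0, 1.0, 1.0, 3.0]))
        np.testing.assert_allclose(fit.leverage, 0.5)  # n h / p = 1 -> delta 1
        hc4 = hc_covariance(fit, "HC4")
        hc3_scaled = brute_force_sandwich(X, fit.residuals, fit.leverage, 1.0)
        np.testing.assert_allclose(hc4.cov, hc3_scaled, rtol=1e-12)

    def test_exact_leverage_errors(self):
        # p = n-1 with a lone extreme point drives a leverage to ~1
        X = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        fit = fit_ols(X, np.array([0.0, 1.0, 5.0]))
        assert fit.leverage.max() > 1 - 1e-12
        with pytest.raises(ExactLeverageError):
            hc_covariance(fit, "HC3")


class TestHCInference:
    def test_se_is_sqrt_of_diagonal(self, small_fit):
        cov = hc_covariance(small_fit, "HC4")
        inf = hc_inference(small_fit, cov, k=1, beta_true=0.5)
        assert inf.se == pytest.approx(np.sqrt(cov.cov[1, 1]))
        assert inf.t_stat == pytest.approx(small_fit.beta_hat[1] / inf.se)
        assert inf.method == "HC4"

    def test_matches_statsmodels_hc3_t_inference(self, small_fit):
        sm = pytest.importorskip("statsmodels.api")
        res = sm.OLS(small_fit.y, small_fit.X).fit(
            cov_type="HC3", use_t=True
        )
        inf = hc_inference(small_fit, hc_covariance(small_fit, "HC3"), k=1)
        assert inf.se == pytest.approx(res.bse[1], rel=1e-8)
        assert inf.p_value == pytest.approx(res.pvalues[1], rel=1e-6)

    def test_hc3_consistent_with_classical_at_large_n_homoskedastic(self):
        rng = np.random.default_rng(5)
        n = 100_000
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        fit = fit_ols(np.column_stack([np.ones(n), x]), y)
        hc3_se = np.sqrt(hc_covariance(fit, "HC3").cov[1, 1])
        classical_se = np.sqrt(fit.sigma2_hat * fit.xtx_inv[1, 1])
        assert hc3_se == pytest.approx(classical_se, rel=0.02)
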