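import numpy as np
import pytest

from hetsim import (
    BootstrapDistribution,
    bca_ci,
    bootstrap_p_value,
    fit_ols,
    pairs_resample,
    percentile_ci,
    wild_resample,
)
from hetsim.bootstrap_inference import (
    DegenerateDistributionError,
    jackknife_slopes,
)


def make_dist(beta_star, estimate=0.0, t=0.0, scheme="pairs", se_star=None):
    beta_star = np.asarray(beta_star, dtype=float)
    if se_star is None:
        se_star = np.ones_like(beta_star)  # unit studentization
    return BootstrapDistribution(
        scheme=scheme, B=len(beta_star), beta_star=beta_star,
        original_estimate=estimate, original_t=t, se_star=np.asarray(se_star),
    )


class TestPairsResample:
    def test_perfect_fit_reproduces_estimate(self, rng):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        y = 2.0 + 3.0 * np.arange(6.0)  # zero residuals
        dist = pairs_resample(X, y, B=50, rng=rng)
        np.testing.assert_allclose(dist.beta_star, 3.0, atol=1e-9)

    def test_bootstrap_sd_tracks_classical_se(self, rng):
        n = 50
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_ols(X, y)
        dist = pairs_resample(X, y, B=1000, rng=rng, fit=fit)
        classical_se = np.sqrt(fit.sigma2_hat * fit.xtx_inv[1, 1])
        assert np.std(dist.beta_star, ddof=1) == pytest.approx(
            classical_se, rel=0.15
        )

    def test_deterministic_given_seed(self, small_fit):
        d1 = pairs_resample(
            small_fit.X, small_fit.y, 100, np.random.default_rng(3)
        )
        d2 = pairs_resample(
            small_fit.X, small_fit.y, 100, np.random.default_rng(3)
        )
        np.testing.assert_array_equal(d1.beta_star, d2.beta_star)


class _AllPlusRng:
    """Stub RNG: Rademacher weights all +1."""

    def integers(self, low, high, size=None):
        return np.ones(size, dtype=int)


class TestWildResample:
    def test_zero_residuals_degenerate(self, rng):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        fit = fit_ols(X, 1.0 + 2.0 * np.arange(5.0))
        dist = wild_resample(fit, B=20, rng=rng)
        np.testing.assert_allclose(dist.beta_star, 2.0, atol=1e-9)
        with pytest.raises(DegenerateDistributionError):
            bootstrap_p_value(dist)

    def test_all_plus_weights_match_hand_refit(self, rng):
        """v* = +1 for every case: y* = yhat + r/(1-h), beta* by lstsq."""
        X = np.column_stack([np.ones(3), [0.0, 1.0, 3.0]])
        y = np.array([1.0, 2.0, 2.5])
        fit = fit_ols(X, y)
        dist = wild_resample(fit, B=1, rng=_AllPlusRng())
        ystar = fit.fitted + fit.residuals / (1.0 - fit.leverage)
        expected, *_ = np.linalg.lstsq(X, ystar, rcond=None)
        assert dist.beta_star[0] == pytest.approx(expected[1], abs=1e-10)

    def test_mean_beta_star_near_original(self, small_fit):
        dist = wild_resample(small_fit, B=10_000, rng=np.random.default_rng(1))
        se = np.std(dist.beta_star, ddof=1)
        assert dist.beta_star.mean() == pytest.approx(
            small_fit.beta_hat[1], abs=4 * se / 100
        )

    def test_design_matrix_unchanged(self, small_fit):
        before = small_fit.X.copy()
        wild_resample(small_fit, B=100, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(small_fit.X, before)


class TestBootstrapPValue:
    def test_upper_edge_all_exceed(self):
        # every |t*| >= |t| = 0 -> p = (B+1)/(B+1) = 1
        dist = make_dist([1.0, -1.0, 2.0, -2.0], estimate=0.0, t=0.0)
        assert bootstrap_p_value(dist) == 1.0

    def test_lower_edge_none_exceed(self):
        dist = make_dist([0.1, -0.1, 0.05, -0.05], estimate=0.0, t=100.0)
        assert bootstrap_p_value(dist) == pytest.approx(1.0 / 5.0)

    def test_count_arithmetic_on_four_draw_toy(self):
        """B=4, t^2 = 4, t*^2 = (1, 5, 3, 9) -> p = (2+1)/5 = 0.6."""
        beta_star = np.array([1.0, -np.sqrt(5), np.sqrt(3), 3.0])
        dist = make_dist(beta_star, estimate=0.0, t=2.0)  # unit SEs
        assert bootstrap_p_value(dist) == pytest.approx(0.6)

    def test_pooled_denominator_variant(self):
        beta_star = np.array([1.0, -np.sqrt(5), np.sqrt(3), 3.0])
        s = np.std(beta_star, ddof=1)
        dist = make_dist(beta_star, estimate=0.0, t=2.0 / s)
        assert bootstrap_p_value(dist, denominator="pooled") == pytest.approx(0.6)

    def test_studentization_uses_per_resample_scale(self, rng):
        """Doubling one draw's SE halves its |t*| and can flip the count."""
        beta_star = np.array([3.0, 0.1, 0.1, 0.1])
        lo = bootstrap_p_value(make_dist(beta_star, t=2.0))  # t*_1 = 3 >= 2
        hi = bootstrap_p_value(
            make_dist(beta_star, t=2.0, se_star=[2.0, 1.0, 1.0, 1.0])
        )  # t*_1 = 1.5 < 2
        assert lo == pytest.approx(2.0 / 5.0)
        assert hi == pytest.approx(1.0 / 5.0)


class TestPercentileCI:
    def test_permutation_of_integers_closed_form(self, rng):
        values = rng.permutation(np.arange(1.0, 1001.0))
        dist = make_dist(values)
        lo, hi = percentile_ci(dist)
        # (B+1)q plotting position: indices 25.025 and 975.975 of 1..1000
        assert lo == pytest.approx(25.025)
        assert hi == pytest.approx(975.975)

    def test_constant_distribution_gives_point_interval(self):
        dist = make_dist(np.full(100, 3.14))
        assert percentile_ci(dist) == (pytest.approx(3.14), pytest.approx(3.14))

    def test_symmetric_distribution_gives_symmetric_interval(self, rng):
        v = rng.standard_normal(500)
        dist = make_dist(np.r_[v, -v])
        lo, hi = percentile_ci(dist)
        assert lo == pytest.approx(-hi, abs=1e-12)


class TestBCa:
    def _symmetric_fit(self):
        # symmetric x and residual pattern -> jackknife slopes symmetric
        # about their mean -> acceleration exactly 0
        X = np.column_stack([np.ones(4), [-2.0, -1.0, 1.0, 2.0]])
        e = 0.5
        y = X[:, 1] + np.array([e, -e, -e, e])
        return fit_ols(X, y)

    def test_equals_percentile_when_unbiased_and_unaccelerated(self, rng):
        fit = self._symmetric_fit()
        b = fit.beta_hat[1]
        offsets = rng.standard_normal(500)
        beta_star = np.r_[b + offsets, b - offsets]  # exactly half below b
        dist = make_dist(beta_star, estimate=b)
        bca = bca_ci(dist, fit)
        lo, hi = percentile_ci(dist)
        assert bca.z0 == pytest.approx(0.0, abs=1e-12)
        assert bca.accel == pytest.approx(0.0, abs=1e-12)
        assert not bca.flagged
        assert bca.low == pytest.approx(lo)
        assert bca.high == pytest.approx(hi)

    def test_one_sided_distribution_is_clamped_and_flagged(self):
        fit = self._symmetric_fit()
        dist = make_dist(
            fit.beta_hat[1] + 1.0 + np.arange(200.0), estimate=fit.beta_hat[1]
        )
        bca = bca_ci(dist, fit)
        assert bca.flagged
        assert np.isfinite(bca.low) and np.isfinite(bca.high)

    def test_jackknife_matches_explicit_leave_one_out(self, two_pred_fit):
        theta = jackknife_slopes(two_pred_fit, k=1)
        n = two_pred_fit.n
        for i in range(n):
            keep = np.arange(n) != i
            expected, *_ = np.linalg.lstsq(
                two_pred_fit.X[keep], two_pred_fit.y[keep], rcond=None
            )
            assert theta[i] == pytest.approx(expected[1], abs=1e-10)

    def test_matches_scipy_bca_reference(self, rng):
        """Cross-implementation check against scipy.stats.bootstrap (BCa).

        Different resample streams, so agreement is to Monte-Carlo
        resolution of the order statistics, not exact.
        """
        from scipy import stats

        n = 30
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n) * (1 + 0.5 * np.abs(x))
        X = np.column_stack([np.ones(n), x])
        fit = fit_ols(X, y)
        B = 4000
        dist = pairs_resample(X, y, B=B, rng=rng, fit=fit)
        bca = bca_ci(dist, fit)

        def slope(xs, ys):
            xs = np.asarray(xs)
            A = np.column_stack([np.ones(len(xs)), xs])
            return np.linalg.lstsq(A, ys, rcond=None)[0][1]

        ref = stats.bootstrap(
            (x, y), slope, paired=True, vectorized=False, method="BCa",
            n_resamples=B, random_state=np.random.default_rng(99),
        ).confidence_interval
        spread = np.std(dist.beta_star, ddof=1)
        tol = 4.0 * spread / np.sqrt(B) + 0.02 * spread
        assert bca.low == pytest.approx(ref.low, abs=tol)
        assert bca.high == pytest.approx(ref.high, abs=tol)
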