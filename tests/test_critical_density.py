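import math

import numpy as np
import pytest

from sdmon.critical_density import (
    FitError,
    critical_density,
    estimate_critical_density,
    fit_density_violation_regression,
    prediction_interval,
    sample_skewness,
)
from sdmon.synthetic import simulate_regression_data


def exact_fit(beta0=0.02, beta1=0.004, v_max=10):
    v = np.arange(v_max + 1, dtype=float)
    return fit_density_violation_regression(v, beta0 + beta1 * v)


class TestRegressionFit:
    def test_noiseless_data_recovered_exactly(self):
        fit = exact_fit()
        assert fit.beta0 == pytest.approx(0.02)
        assert fit.beta1 == pytest.approx(0.004)
        assert fit.s == pytest.approx(0.0, abs=1e-12)

    def test_constant_regressor_rejected(self):
        with pytest.raises(FitError):
            fit_density_violation_regression([3.0] * 10, np.arange(10.0))

    def test_too_few_observations_rejected(self):
        with pytest.raises(FitError):
            fit_density_violation_regression([0.0, 1.0], [0.0, 1.0])

    def test_estimates_within_three_se_of_truth(self):
        v, rho = simulate_regression_data(
            beta0=0.02, beta1=0.004, noise_sigma=0.003, n_points=1000, seed=11
        )
        fit = fit_density_violation_regression(v, rho)
        se_b0 = fit.s * math.sqrt(1 / fit.n_obs + fit.v_bar**2 / fit.s_vv)
        se_b1 = fit.s / math.sqrt(fit.s_vv)
        assert abs(fit.beta0 - 0.02) < 3 * se_b0
        assert abs(fit.beta1 - 0.004) < 3 * se_b1

    def test_residuals_sum_to_zero_and_line_through_means(self, rng):
        v = rng.integers(0, 15, size=200).astype(float)
        rho = 0.01 + 0.002 * v + rng.normal(0, 0.004, 200)
        fit = fit_density_violation_regression(v, rho)
        resid = rho - fit.beta0 - fit.beta1 * v
        assert abs(resid.sum()) < 1e-10
        assert fit.predict(v.mean()) == pytest.approx(rho.mean())

    def test_matches_statsmodels_ols(self, rng):
        """Independent cross-check of the closed-form fit and interval."""
        sm = pytest.importorskip("statsmodels.api")
        v = rng.integers(0, 12, size=300).astype(float)
        rho = 0.02 + 0.004 * v + rng.normal(0, 0.003, 300)
        fit = fit_density_violation_regression(v, rho)
        model = sm.OLS(rho, sm.add_constant(v)).fit()
        assert fit.beta0 == pytest.approx(model.params[0])
        assert fit.beta1 == pytest.approx(model.params[1])
        assert fit.s**2 == pytest.approx(model.mse_resid)
        frame = model.get_prediction([1.0, 0.0]).summary_frame(alpha=0.05)
        lo, hi = prediction_interval(fit, 0.0, 0.95)
        assert lo == pytest.approx(frame["obs_ci_lower"][0])
        assert hi == pytest.approx(frame["obs_ci_upper"][0])


class TestPredictionInterval:
    def test_zero_noise_collapses_to_point(self):
        fit = exact_fit()
        assert prediction_interval(fit, 3.0) == (fit.predict(3.0),) * 2

    def test_symmetric_about_fitted_mean(self, rng):
        v, rho = simulate_regression_data(n_points=200, seed=3)
        fit = fit_density_violation_regression(v, rho)
        for v_star in (0.0, 2.0, 7.5):
            lo, hi = prediction_interval(fit, v_star)
            assert 0.5 * (lo + hi) == pytest.approx(fit.predict(v_star))

    def test_width_minimized_at_mean_regressor(self):
        v, rho = simulate_regression_data(n_points=200, seed=4)
        fit = fit_density_violation_regression(v, rho)

        def width(v_star):
            lo, hi = prediction_interval(fit, v_star)
            return hi - lo

        offsets = [0.0, 1.0, 2.0, 5.0]
        widths = [width(fit.v_bar + d) for d in offsets]
        assert widths == sorted(widths)
        assert width(fit.v_bar - 3.0) > width(fit.v_bar)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            prediction_interval(exact_fit(), 0.0, level=1.0)

    def test_empirical_coverage_near_nominal(self):
        """~95% of fresh observations at v* fall inside the 95% interval."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            v = rng.integers(0, 11, size=80).astype(float)
            rho = 0.02 + 0.004 * v + rng.normal(0, 0.003, 80)
            fit = fit_density_violation_regression(v, rho)
            fresh = 0.02 + rng.normal(0, 0.003)  # new observation at v*=0
            lo, hi = prediction_interval(fit, 0.0, 0.95)
            hits += lo <= fresh <= hi
        assert 0.93 <= hits / n_rep <= 0.97


class TestCriticalDensity:
    def test_noiseless_fit_gives_intercept(self):
        res = critical_density(exact_fit())
        assert res.rho_c == pytest.approx(0.02)
        assert res.pi_lower == res.pi_upper == pytest.approx(0.02)

    def test_below_intercept_with_noise(self):
        for seed in range(20):
            v, rho = simulate_regression_data(n_points=300, seed=seed)
            res = estimate_critical_density(v, rho)
            assert 0.0 <= res.rho_c < res.fit.beta0

    def test_clamped_at_zero(self):
        # tiny sample with huge spread drives the lower bound negative
        v = np.array([0.0, 1.0, 2.0, 3.0])
        rho = np.array([0.0, 0.5, 0.1, 0.9])
        res = estimate_critical_density(v, rho)
        assert res.pi_lower < 0.0
        assert res.rho_c == 0.0

    def test_non_increasing_in_level(self):
        v, rho = simulate_regression_data(n_points=300, seed=9)
        fit = fit_density_violation_regression(v, rho)
        rho_cs = [critical_density(fit, level=lv).rho_c
                  for lv in (0.80, 0.90, 0.95, 0.99)]
        assert rho_cs == sorted(rho_cs, reverse=True)

    def test_converges_to_truth_with_large_sample(self):
        """Parameter recovery on data generated by the model itself."""
        v, rho = simulate_regression_data(
            beta0=0.02, beta1=0.004, noise_sigma=0.003,
            n_points=10_000, seed=5,
        )
        fit = fit_density_violation_regression(v, rho)
        se_b0 = fit.s * math.sqrt(1 / fit.n_obs + fit.v_bar**2 / fit.s_vv)
        assert abs(fit.beta0 - 0.02) < 3 * se_b0


class TestSampleSkewness:
    def test_symmetric_sample_is_zero(self):
        assert sample_skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0)

    def test_matches_closed_form_third_moment(self):
        x = np.array([0.0, 0.0, 1.0])
        n = len(x)
        m2 = np.mean((x - x.mean()) ** 2)
        m3 = np.mean((x - x.mean()) ** 3)
        expected = (m3 / m2**1.5) * math.sqrt(n * (n - 1)) / (n - 2)
        assert sample_skewness(x) == pytest.approx(expected)
        assert sample_skewness(x) > 0

    def test_large_normal_sample_near_zero(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        assert abs(sample_skewness(x)) < 0.05

    def test_constant_series_rejected(self):
        with pytest.raises(FitError):
            sample_skewness([2.0, 2.0, 2.0])
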