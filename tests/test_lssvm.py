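import warnings

import numpy as np
import pandas as pd
import pytest

from aerowarn.bbode import BBODEConfig
from aerowarn.ceemd import CEEMDConfig
from aerowarn.lssvm import (
    ForecastTask,
    Standardizer,
    fit,
    forecast_pipeline,
    make_lag_matrix,
    rbf_kernel,
    tune,
)
from aerowarn.metrics import point_metrics
from aerowarn.synthetic import PollutantSeries, SyntheticSpec, generate_series


def _kernel_ridge_with_bias(X, y, sigma, gamma):
    """Independent oracle: two-step partitioned solve of the same model."""
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2 * sigma**2))
    C = K + np.eye(len(y)) / gamma
    Cinv = np.linalg.inv(C)
    one = np.ones(len(y))
    b = float(one @ Cinv @ y) / float(one @ Cinv @ one)
    alpha = Cinv @ (y - b)
    return b, alpha


class TestRBFKernel:
    def test_zero_distance_gives_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rbf_kernel(x, x, 0.7) == pytest.approx(1.0)

    def test_distance_sqrt2_sigma_gives_inverse_e(self):
        sigma = 1.3
        xi = np.zeros(2)
        xj = np.array([np.sqrt(2.0) * sigma, 0.0])
        assert rbf_kernel(xi, xj, sigma) == pytest.approx(np.exp(-1.0))

    def test_matches_direct_formula_on_random_pairs(self, rng):
        for _ in range(10):
            xi, xj = rng.normal(size=(2, 4))
            sigma = rng.uniform(0.1, 5)
            expected = np.exp(-np.sum((xj - xi) ** 2) / (2 * sigma**2))
            assert rbf_kernel(xi, xj, sigma) == pytest.approx(expected, rel=1e-12)

    def test_invalid_sigma_or_dims_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([1.0], [2.0], 0.0)
        with pytest.raises(ValueError):
            rbf_kernel([1.0, 2.0], [1.0], 1.0)

    def test_kernel_matrix_positive_semidefinite(self, rng):
        X = rng.normal(size=(30, 3))
        K = rbf_kernel(X, X, 1.5)
        eig = np.linalg.eigvalsh(K)
        assert eig.min() >= -1e-10


class TestFit:
    def test_matches_independent_partitioned_solver(self, rng):
        for _ in range(20):
            X = rng.normal(size=(20, 3))
            y = rng.normal(size=20)
            sigma = rng.uniform(0.5, 3)
            gamma = rng.uniform(1, 100)
            m = fit(X, y, sigma, gamma)
            b, alpha = _kernel_ridge_with_bias(X, y, sigma, gamma)
            assert m.bias == pytest.approx(b, abs=1e-8)
            np.testing.assert_allclose(m.dual_coefficients, alpha, atol=1e-8)

    def test_interpolation_limit_at_huge_gamma(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        m = fit(X, y, 1.0, 1e8)
        np.testing.assert_allclose(m.predict(X), y, rtol=1e-4, atol=1e-4)

    def test_repeated_single_point_predicts_mean_target(self):
        X = np.tile([[1.0, 2.0]], (6, 1))
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit(X, y, 1.0, 10.0)
        assert m.predict([[1.0, 2.0]])[0] == pytest.approx(y.mean(), rel=1e-6)

    def test_prediction_invariant_under_row_permutation(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        perm = rng.permutation(15)
        m1 = fit(X, y, 1.2, 50.0)
        m2 = fit(X[perm], y[perm], 1.2, 50.0)
        q = rng.normal(size=(5, 2))
        np.testing.assert_allclose(m1.predict(q), m2.predict(q), atol=1e-8)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit(np.zeros((1, 2)), [1.0], 1.0, 1.0)
        with pytest.raises(ValueError):
            fit(np.zeros((3, 2)), np.zeros(3), -1.0, 1.0)


class TestLagMatrix:
    def test_rows_are_consecutive_lags(self):
        X, y = make_lag_matrix([1.0, 2.0, 3.0, 4.0, 5.0], 2)
        np.testing.assert_array_equal(X, [[1, 2], [2, 3], [3, 4]])
        np.testing.assert_array_equal(y, [3, 4, 5])

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            make_lag_matrix([1.0, 2.0], 3)


class TestTune:
    def _toy(self, rng, n=150):
        X = rng.uniform(-2, 2, (n, 2))
        centers = rng.normal(size=(5, 2))
        y = np.sum(np.exp(-((X[:, None, :] - centers) ** 2).sum(-1)), axis=1)
        return X, y + rng.normal(0, 0.05, n)

    def test_beats_random_hyperparameter_draws(self, rng):
        X, y = self._toy(rng)
        sigma, gamma = tune(X, y)

        def holdout_mse(s, g):
            n_val = 30
            sc = Standardizer(X[:-n_val], y[:-n_val])
            m = fit(sc.fx(X[:-n_val]), sc.fy(y[:-n_val]), s, g)
            pred = sc.inv_y(m.predict(sc.fx(X[-n_val:])))
            return float(np.mean((y[-n_val:] - pred) ** 2))

        tuned = holdout_mse(sigma, gamma)
        draws = 10.0 ** rng.uniform([-2, -1], [2, 6], (20, 2))
        assert all(tuned <= holdout_mse(s, g) + 1e-12 for s, g in draws)

    def test_recovers_low_error_on_rbf_generated_data(self, rng):
        X, y = self._toy(rng, n=200)
        cfg = BBODEConfig(pop_size=15, max_iter=40, seed=1)
        sigma, gamma = tune(X[:150], y[:150], bbode_config=cfg)
        sc = Standardizer(X[:150], y[:150])
        m = fit(sc.fx(X[:150]), sc.fy(y[:150]), sigma, gamma)
        mse = float(np.mean((y[150:] - sc.inv_y(m.predict(sc.fx(X[150:])))) ** 2))
        assert mse <= 2 * 0.05**2

    def test_constant_target_returns_box_midpoint_with_warning(self):
        X = np.arange(20.0)[:, None]
        with pytest.warns(UserWarning):
            sigma, gamma = tune(X, np.full(20, 3.0))
        assert sigma == pytest.approx(1.0)  # log-box midpoint of [0.01, 100]


def _ar_series(n=400, phi=0.95, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = 80.0
    for i in range(1, n):
        x[i] = 2.0 + phi * x[i - 1] + (rng.normal(0, noise) if noise else 0.0)
    stamps = pd.date_range("2015-01-01", periods=n, freq="h")
    return PollutantSeries("PM2.5", stamps, np.clip(x, 0, None))


class TestForecastPipeline:
    CEEMD = CEEMDConfig(ensemble_size=5, seed=0)
    BBODE = BBODEConfig(pop_size=12, max_iter=25, seed=0)

    def test_noiseless_autoregressive_series_forecast_nearly_exact(self):
        task = ForecastTask(_ar_series(noise=0.0), lag_order=5)
        res = forecast_pipeline(task, self.CEEMD, self.BBODE)
        mape = point_metrics(res.actual, res.predicted).mape
        assert mape < 1.0

    def test_identical_seeds_give_identical_predictions(self):
        task = ForecastTask(_ar_series(noise=1.0, seed=3), lag_order=5)
        r1 = forecast_pipeline(task, self.CEEMD, self.BBODE)
        r2 = forecast_pipeline(task, self.CEEMD, self.BBODE)
        np.testing.assert_array_equal(r1.predicted, r2.predicted)

    def test_denoising_lowers_rmse_on_noisy_series(self):
        s = generate_series(SyntheticSpec(n_hours=500, noise_scale=12.0,
                                          ar_coefficient=0.6, seed=8))
        task = ForecastTask(s, lag_order=5)
        with_d = forecast_pipeline(task, self.CEEMD, self.BBODE, use_denoise=True)
        without = forecast_pipeline(task, self.CEEMD, self.BBODE, use_denoise=False)
        rmse_d = point_metrics(with_d.actual, np.clip(with_d.predicted, 0, None)).rmse
        rmse_r = point_metrics(without.actual, np.clip(without.predicted, 0, None)).rmse
        assert rmse_d < rmse_r

    def test_tuned_pipeline_not_worse_than_default_parameters(self):
        s = generate_series(SyntheticSpec(n_hours=500, seed=5))
        task = ForecastTask(s, lag_order=5)
        tuned = forecast_pipeline(task, self.CEEMD, self.BBODE, tune_params=True)
        fixed = forecast_pipeline(task, self.CEEMD, self.BBODE, tune_params=False)
        mape_t = point_metrics(tuned.actual, tuned.predicted).mape
        mape_f = point_metrics(fixed.actual, fixed.predicted).mape
        assert mape_t <= mape_f

    def test_split_leaving_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            ForecastTask(_ar_series(n=400), lag_order=5, split_index=30)
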