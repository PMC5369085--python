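"""Least-squares support vector regression and the hybrid forecaster.

LSSVM replaces the inequality constraints of classic support vector
regression with equality constraints and a squared loss, so fitting
reduces to one linear solve of the bordered dual system

    [ 0   1^T          ] [ b     ]   [ 0 ]
    [ 1   K + I/gamma  ] [ alpha ] = [ y ]

with RBF kernel K(x_i, x_j) = exp(-||x_i - x_j||^2 / (2 sigma^2)).
Predictions are b + sum_m alpha_m K(x_m, x*).  The kernel width sigma
and regularization gamma are the two hyperparameters the BBODE
optimizer searches (in log10 space) by minimizing mean squared error
on a chronological holdout.

:func:`forecast_pipeline` chains the full hybrid point forecaster:
CEEMD decomposition, removal of the noise-dominated first mode, lag
embedding, hyperparameter tuning, fitting and static one-step-ahead
prediction over the test rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgWarning, lstsq, solve
from scipy.spatial.distance import cdist

from aerowarn.bbode import BBODEConfig, optimize
from aerowarn.ceemd import CEEMDConfig, ceemd, denoise
from aerowarn.synthetic import PollutantSeries


def rbf_kernel(xi, xj, sigma: float):
    """Gaussian kernel exp(-||xj - xi||^2 / (2 sigma^2)).

    Accepts vectors or matrices (row = sample); returns a scalar or the
    Gram matrix accordingly.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    xj = np.atleast_2d(np.asarray(xj, dtype=float))
    if xi.shape[1] != xj.shape[1]:
        raise ValueError("inputs must have equal dimension")
    d2 = cdist(xi, xj, "sqeuclidean")
    K = np.exp(-d2 / (2.0 * sigma**2))
    return float(K[0, 0]) if K.size == 1 else K


@dataclass
class LSSVMModel:
    """Fitted dual solution: support inputs, coefficients, bias, kernel."""

    train_inputs: np.ndarray
    dual_coefficients: np.ndarray
    bias: float
    sigma: float
    gamma: float

    def __post_init__(self) -> None:
        if len(self.train_inputs) != len(self.dual_coefficients):
            raise ValueError("alpha and train_inputs must have equal length")

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = rbf_kernel(X, self.train_inputs, self.sigma)
        K = np.atleast_2d(K)
        return self.bias + K @ self.dual_coefficients


def fit(X, y, sigma: float, gamma: float) -> LSSVMModel:
    """Solve the LSSVM dual system for (bias, alpha).

    Falls back to a least-squares solve with a warning when the
    bordered system is numerically singular (duplicate rows, extreme
    gamma).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    M = len(y)
    if M < 2:
        raise ValueError("need at least 2 training rows")
    if sigma <= 0 or gamma <= 0:
        raise ValueError("sigma and gamma must be positive")

    K = rbf_kernel(X, X, sigma)
    A = np.empty((M + 1, M + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(M) / gamma
    rhs = np.concatenate([[0.0], y])
    with warnings.catch_warnings():
        warnings.simplefilter("error", LinAlgWarning)
        try:
            sol = solve(A, rhs, assume_a="sym")
        except (np.linalg.LinAlgError, LinAlgWarning, ValueError):
            warnings.warn("singular LSSVM system; using least-squares fallback")
            sol = lstsq(A, rhs)[0]
    return LSSVMModel(X, sol[1:], float(sol[0]), float(sigma), float(gamma))


def make_lag_matrix(values, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Supervised matrix from consecutive lags.

    Row t holds ``(x[t-d], ..., x[t-1])`` with target ``x[t]``.
    """
    x = np.asarray(values, dtype=float)
    if d < 1 or len(x) <= d:
        raise ValueError("need lag order >= 1 and series longer than the lag")
    X = np.column_stack([x[j : len(x) - d + j] for j in range(d)])
    return X, x[d:]


class Standardizer:
    """Z-score transform frozen on training statistics."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.x_mean = X.mean(axis=0)
        self.x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self.y_mean = float(y.mean())
        self.y_std = float(y.std()) or 1.0

    def fx(self, X):
        return (X - self.x_mean) / self.x_std

    def fy(self, y):
        return (y - self.y_mean) / self.y_std

    def inv_y(self, y):
        return y * self.y_std + self.y_mean


#: Hyperparameter search box, in log10: sigma in [0.01, 100], gamma in [0.1, 1e6].
DEFAULT_SEARCH_BOUNDS = ((-2.0, 2.0), (-1.0, 6.0))


def tune(
    X,
    y,
    search_bounds=DEFAULT_SEARCH_BOUNDS,
    bbode_config: BBODEConfig | None = None,
    holdout_fraction: float = 0.2,
) -> tuple[float, float]:
    """Search (sigma, gamma) minimizing holdout MSE with BBODE.

    The last ``holdout_fraction`` of the rows (chronological order, no
    shuffling) is the validation set; the optimizer works on
    (log10 sigma, log10 gamma) inside ``search_bounds``.  A constant
    target is degenerate: the box midpoint is returned with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    b = np.asarray(search_bounds, dtype=float)
    if np.ptp(y) == 0:
        warnings.warn("constant target; returning search-box midpoint")
        mid = b.mean(axis=1)
        return 10.0 ** mid[0], 10.0 ** mid[1]

    n_val = max(1, int(round(holdout_fraction * len(y))))
    Xtr, ytr = X[:-n_val], y[:-n_val]
    Xva, yva = X[-n_val:], y[-n_val:]
    sc = Standardizer(Xtr, ytr)
    Xtr_s, ytr_s = sc.fx(Xtr), sc.fy(ytr)
    Xva_s = sc.fx(Xva)

    def objective(theta):
        theta = np.atleast_2d(theta)
        out = np.empty(len(theta))
        for i, (ls, lg) in enumerate(theta):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = fit(Xtr_s, ytr_s, 10.0**ls, 10.0**lg)
                pred = sc.inv_y(model.predict(Xva_s))
                out[i] = float(np.mean((yva - pred) ** 2))
            except Exception:
                out[i] = np.inf
        return out

    cfg = bbode_config or BBODEConfig(pop_size=20, max_iter=60, seed=0)
    best, _, _ = optimize(objective, b, config=cfg, vectorized=True)
    return 10.0 ** best[0], 10.0 ** best[1]


@dataclass
class ForecastTask:
    """One-step-ahead forecasting setup for a (denoised) series."""

    series: PollutantSeries
    lag_order: int = 5
    split_index: int | None = None  # first test row; default = 80% of rows
    def __post_init__(self) -> None:
        n = len(self.series)
        if self.split_index is None:
            self.split_index = int(0.8 * n)
        n_train_rows = self.split_index - self.lag_order
        if n_train_rows < 10 * self.lag_order:
            raise ValueError("split leaves fewer than 10*d training rows")


@dataclass
class ForecastResult:
    timestamps: object
    actual: np.ndarray
    predicted: np.ndarray
    sigma: float
    gamma: float
    model: LSSVMModel
    standardizer: Standardizer
    denoised: np.ndarray


def forecast_pipeline(
    task: ForecastTask,
    ceemd_config: CEEMDConfig | None = None,
    bbode_config: BBODEConfig | None = None,
    use_denoise: bool = True,
    tune_params: bool = True,
    default_params: tuple[float, float] = (1.0, 100.0),
) -> ForecastResult:
    """Run the full hybrid point forecaster on one series.

    Stage order: CEEMD decomposition of the whole series, removal of
    IMF1, reconstruction, lag-matrix embedding, chronological split,
    hyperparameter tuning on the training rows, final fit, and static
    one-step-ahead prediction over the test rows (true lagged values as
    inputs).
    """
    values = task.series.values
    if use_denoise:
        try:
            imfset = ceemd(values, ceemd_config or CEEMDConfig(ensemble_size=20, seed=0))
            values = denoise(imfset)
        except Exception as exc:  # pragma: no cover - stage tagging only
            raise RuntimeError(f"ceemd stage failed: {exc}") from exc

    try:
        X, y = make_lag_matrix(values, task.lag_order)
    except Exception as exc:
        raise RuntimeError(f"lag-matrix stage failed: {exc}") from exc
    split = task.split_index - task.lag_order
    Xtr, ytr = X[:split], y[:split]
    Xte = X[split:]
    y_actual = task.series.values[task.split_index :]

    if tune_params:
        try:
            sigma, gamma = tune(Xtr, ytr, bbode_config=bbode_config)
        except Exception as exc:
            raise RuntimeError(f"tuning stage failed: {exc}") from exc
    else:
        sigma, gamma = default_params

    sc = Standardizer(Xtr, ytr)
    try:
        model = fit(sc.fx(Xtr), sc.fy(ytr), sigma, gamma)
    except Exception as exc:
        raise RuntimeError(f"fit stage failed: {exc}") from exc
    predicted = sc.inv_y(model.predict(sc.fx(Xte)))

    return ForecastResult(
        timestamps=task.series.timestamps[task.split_index :],
        actual=y_actual,
        predicted=predicted,
        sigma=sigma,
        gamma=gamma,
        model=model,
        standardizer=sc,
        denoised=values,
    )
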