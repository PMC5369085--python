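"""Nonsymmetric prediction intervals for LSSVM via linear smoothing.

An LSSVM with fixed hyperparameters is a *linear smoother*: its fitted
values are linear in the training targets, y_hat = L y.  That opens
the standard central-limit recipe for pointwise prediction intervals:

1. build the smoother matrix L from the bordered dual system;
2. estimate bias by double smoothing, L y_hat - y_hat;
3. estimate the noise variance by smoothing the squared residuals with
   the same smoother, inflated by the degrees-of-freedom correction
   M / (M - tr L);
4. at significance level a, the interval around the bias-corrected
   center is +/- z_{a/2} times the square root of (local noise
   variance + smoother variance), which is nonsymmetric about the raw
   forecast whenever the bias estimate is nonzero.

Coverage probability (CP) and average width (AW) score the intervals:
CP is the fraction of realized values inside their closed interval and
must reach at least 1 - a for the intervals to be valid; AW measures
informativeness (narrower is better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from aerowarn.lssvm import LSSVMModel, rbf_kernel


@dataclass
class PredictionInterval:
    """One pointwise forecasting interval at significance ``a``."""

    lower: float
    upper: float
    center: float
    significance: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def covers(self, y: float) -> bool:
        """Closed-interval membership: boundary values count as covered."""
        return self.lower <= y <= self.upper


@dataclass
class IntervalMetrics:
    cp: float
    aw: float
    significance: float | None = None

    @property
    def valid(self) -> bool | None:
        """CP >= 1 - a, the theoretical validity condition."""
        if self.significance is None:
            return None
        return self.cp >= 1.0 - self.significance


def _bordered_inverse_block(model: LSSVMModel) -> np.ndarray:
    """Columns 1..M of the inverse bordered system matrix."""
    M = len(model.dual_coefficients)
    K = rbf_kernel(model.train_inputs, model.train_inputs, model.sigma)
    A = np.empty((M + 1, M + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(M) / model.gamma
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        Ainv = np.linalg.pinv(A)
    return Ainv[:, 1:]


def smoother_matrix(model: LSSVMModel, X=None) -> np.ndarray:
    """Matrix L with predictions(X) = L @ y_train.

    With ``X=None`` the training smoother is returned, satisfying
    y_hat_train = L y_train exactly.  For new points the rows are built
    from kernel evaluations at those points against the training
    inputs.
    """
    B = _bordered_inverse_block(model)
    if X is None:
        X = model.train_inputs
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Kx = np.atleast_2d(rbf_kernel(X, model.train_inputs, model.sigma))
    G = np.hstack([np.ones((len(X), 1)), Kx])
    return G @ B


def bias_and_variance(
    model: LSSVMModel,
    L: np.ndarray,
    y_train,
) -> tuple[np.ndarray, np.ndarray]:
    """Training-point bias and local noise-variance estimates.

    Bias by double smoothing (L y_hat - y_hat); noise variance by
    smoothing the squared residuals with the same smoother, inflated by
    M / (M - tr L).  Negative smoothed variances are floored at zero
    with a warning.
    """
    y = np.asarray(y_train, dtype=float).ravel()
    yhat = L @ y
    bias = L @ yhat - yhat
    resid2 = (y - yhat) ** 2
    M = len(y)
    dof = M / max(M - float(np.trace(L)), 1e-12)
    var = dof * (L @ resid2)
    if np.any(var < 0):
        warnings.warn("negative smoothed variance floored at 0")
        var = np.clip(var, 0.0, None)
    return bias, var


def predict_interval(
    model: LSSVMModel,
    x_points,
    a: float,
    y_train,
) -> list[PredictionInterval]:
    """Pointwise prediction intervals at significance level ``a``.

    The center is the bias-corrected forecast; the half-width is
    z_{a/2} times the square root of the local noise variance plus the
    smoother-row variance Sum_j L*_j^2 sigma^2(x_j).  Width is strictly
    decreasing in ``a``.
    """
    if not 0 < a < 1:
        raise ValueError("significance level must lie in (0, 1)")
    y = np.asarray(y_train, dtype=float).ravel()
    Ltr = smoother_matrix(model)
    _, var_tr = bias_and_variance(model, Ltr, y)

    X = np.atleast_2d(np.asarray(x_points, dtype=float))
    Lx = smoother_matrix(model, X)
    yhat = model.predict(X)
    bias = Lx @ (Ltr @ y) - yhat

    resid2 = (y - Ltr @ y) ** 2
    M = len(y)
    dof = M / max(M - float(np.trace(Ltr)), 1e-12)
    var_noise = np.clip(dof * (Lx @ resid2), 0.0, None)
    var_smoother = (Lx**2) @ var_tr
    se = np.sqrt(var_noise + var_smoother)

    z = norm.ppf(1.0 - a / 2.0)
    center = yhat - bias
    return [
        PredictionInterval(float(c - z * s), float(c + z * s), float(c), a)
        for c, s in zip(center, se)
    ]


def score_intervals(intervals, actuals, significance: float | None = None) -> IntervalMetrics:
    """Coverage probability and average width of a batch of intervals."""
    actuals = np.asarray(actuals, dtype=float).ravel()
    if len(intervals) != len(actuals):
        raise ValueError("intervals and actuals must have equal length")
    covered = np.array([iv.covers(y) for iv, y in zip(intervals, actuals)])
    widths = np.array([iv.width for iv in intervals])
    a = significance if significance is not None else intervals[0].significance
    return IntervalMetrics(float(covered.mean()), float(widths.mean()), a)
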