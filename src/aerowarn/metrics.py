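"""Point-forecast accuracy metrics and the Diebold-Mariano test.

MAE, MAPE (in percent), RMSE and R^2 summarize point-forecast
accuracy; the Diebold-Mariano statistic compares two competing
forecasts through the mean of their loss differential
V_t = F(e_t^(1)) - F(e_t^(2)),

    DM = mean(V) / sqrt(S^2 / t),

which is asymptotically standard normal under the null of equal
accuracy; |DM| > z_{alpha/2} rejects.  Positive DM means the first
model's losses exceed the second's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass
class ForecastMetrics:
    mae: float
    mape: float | None  # percent; None when an actual value is zero
    rmse: float
    r2: float


@dataclass
class DMResult:
    statistic: float | None
    loss: str
    degenerate: bool = False

    def reject(self, alpha: float = 0.05) -> bool:
        """Two-sided decision at level ``alpha``; degenerate never rejects."""
        if self.degenerate or self.statistic is None:
            return False
        return bool(abs(self.statistic) > norm.ppf(1.0 - alpha / 2.0))


def point_metrics(actual, predicted, relative_rmse: bool = False) -> ForecastMetrics:
    """MAE, MAPE (%), RMSE and R^2 of a point forecast.

    RMSE is reported in concentration units; ``relative_rmse=True``
    instead computes sqrt(mean(((y - y') / y)^2)).  MAPE (and relative
    RMSE) are undefined when an actual value is zero and are reported
    as None with a warning.
    """
    y = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if len(y) != len(p) or len(y) < 1:
        raise ValueError("actual and predicted must have equal length >= 1")
    err = y - p
    mae = float(np.mean(np.abs(err)))
    if np.any(y == 0):
        warnings.warn("zero actual value; MAPE undefined")
        mape = None
        rel = None
    else:
        mape = float(np.mean(np.abs(err / y)) * 100.0)
        rel = float(np.sqrt(np.mean((err / y) ** 2)))
    rmse = rel if relative_rmse else float(np.sqrt(np.mean(err**2)))
    if rmse is None:
        raise ValueError("relative RMSE undefined with zero actual values")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else (1.0 if mae == 0 else 0.0)
    return ForecastMetrics(mae, mape, rmse, r2)


def dm_test(errors1, errors2, loss: str = "absolute") -> DMResult:
    """Diebold-Mariano comparison of two forecast-error series.

    ``loss`` is ``"absolute"`` or ``"squared"``.  Identical losses (or
    any constant loss differential) make the variance zero and the
    statistic undefined; such cases are flagged degenerate and never
    reject.
    """
    e1 = np.asarray(errors1, dtype=float).ravel()
    e2 = np.asarray(errors2, dtype=float).ravel()
    if len(e1) != len(e2) or len(e1) < 2:
        raise ValueError("error series must have equal length >= 2")
    if loss == "absolute":
        V = np.abs(e1) - np.abs(e2)
    elif loss == "squared":
        V = e1**2 - e2**2
    else:
        raise ValueError("loss must be 'absolute' or 'squared'")
    t = len(V)
    s2 = float(np.var(V, ddof=1))
    if s2 == 0:
        return DMResult(None, loss, degenerate=True)
    stat = float(np.mean(V) / np.sqrt(s2 / t))
    return DMResult(stat, loss)
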