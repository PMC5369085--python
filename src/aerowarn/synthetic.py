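"""Synthetic hourly pollutant series and bundled worked-example tables.

Real regulatory-grade monitors produce hourly concentration series that
are positive, right-skewed, strongly autocorrelated, carry a diurnal
cycle and show occasional pollution spikes.  :func:`generate_series`
emulates exactly those qualitative features so that every downstream
stage (decomposition, forecasting, interval calibration, evaluation)
can be exercised without access to any monitoring network.

The package also ships, as plain CSV package data, the small worked
example tables used throughout the evaluation module: criterion level
boundaries, cloud parameters, pseudo-bound regressions, entropy-AHP
weights and nine sample forecast vectors with their reference
evaluation results.  :func:`load_fixture` returns them verbatim as
DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: The six pollutant criteria handled by the package, in conventional order.
CRITERIA = ("PM2.5", "PM10", "O3", "CO", "NO2", "SO2")

#: Roman numerals of the six air-quality levels, best to worst.
LEVELS = ("I", "II", "III", "IV", "V", "VI")

_FIXTURES = (
    "criteria_bounds",
    "cloud_params",
    "pseudo_bounds",
    "weights",
    "eval_samples",
    "eval_results",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic hourly pollutant series.

    Parameters
    ----------
    n_hours:
        Series length; at least 48 so a diurnal cycle is observable.
    baseline:
        Mean concentration level in ug/m3 (must be positive).
    diurnal_amplitude:
        Amplitude of the 24 h sinusoidal cycle, ug/m3.
    ar_coefficient:
        AR(1) coefficient of the additive noise, in [0, 1).
    noise_scale:
        Marginal standard deviation of the AR(1) noise, ug/m3.
    spike_rate:
        Probability per hour of an exponential-magnitude pollution spike.
    spike_scale:
        Mean spike magnitude, ug/m3.
    seed:
        Seed for the generator; equal seeds give identical series.
    """

    n_hours: int = 2000
    baseline: float = 40.0
    diurnal_amplitude: float = 8.0
    ar_coefficient: float = 0.8
    noise_scale: float = 10.0
    spike_rate: float = 0.01
    spike_scale: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hours < 48:
            raise ValueError("n_hours must be >= 48")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.noise_scale < 0 or self.spike_rate < 0 or self.spike_scale < 0:
            raise ValueError("noise_scale, spike_rate, spike_scale must be >= 0")
        if self.diurnal_amplitude < 0:
            raise ValueError("diurnal_amplitude must be >= 0")


@dataclass
class PollutantSeries:
    """A timestamped concentration vector for one pollutant criterion."""

    criterion: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "value": self.values})

    def to_csv(self, path) -> None:
        """Write a two-column ``timestamp,value`` CSV with ISO-8601 stamps."""
        self.to_frame().to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")

    @classmethod
    def from_csv(cls, path, criterion: str = "PM2.5") -> "PollutantSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        return cls(criterion, pd.DatetimeIndex(df["timestamp"]), df["value"].to_numpy())


def generate_series(
    spec: SyntheticSpec,
    criterion: str = "PM2.5",
    start: str = "2015-01-01",
) -> PollutantSeries:
    """Generate a pollutant-like hourly series from ``spec``.

    The model is ``baseline + diurnal sinusoid (24 h) + AR(1) Gaussian
    noise + exponential-magnitude spikes``, clipped at zero.  The AR(1)
    noise is scaled so its *marginal* standard deviation equals
    ``noise_scale``, which keeps the lag-1 autocorrelation of the sum
    close to ``ar_coefficient`` for long series.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_hours
    t = np.arange(n)
    diurnal = spec.diurnal_amplitude * np.sin(2 * np.pi * t / 24.0)

    phi = spec.ar_coefficient
    innov_sd = spec.noise_scale * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, n) if spec.noise_scale > 0 else np.zeros(n)
    noise = np.empty(n)
    prev = rng.normal(0.0, spec.noise_scale) if spec.noise_scale > 0 else 0.0
    for i in range(n):
        prev = phi * prev + eps[i]
        noise[i] = prev

    spikes = np.zeros(n)
    if spec.spike_rate > 0:
        hit = rng.random(n) < spec.spike_rate
        spikes[hit] = rng.exponential(spec.spike_scale, hit.sum())

    values = np.clip(spec.baseline + diurnal + noise + spikes, 0.0, None)
    stamps = pd.date_range(start, periods=n, freq="h")
    return PollutantSeries(criterion, stamps, values)


def load_fixture(name: str) -> pd.DataFrame:
    """Return one of the bundled worked-example tables verbatim.

    ``name`` must be one of ``criteria_bounds`` (level upper boundaries
    per criterion, ug/m3), ``cloud_params`` (Ex, En, He per
    criterion x level), ``pseudo_bounds`` (quadratic coefficients and
    extrapolated level-VI bound per criterion), ``weights`` (AHP weight
    z, entropy, entropy weight omega and combined weight W per
    criterion), ``eval_samples`` (nine sample forecast vectors) or
    ``eval_results`` (their reference certainty degrees and levels).
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {_FIXTURES}")
    ref = resources.files("aerowarn.fixtures").joinpath(f"{name}.csv")
    with ref.open("r") as fh:
        return pd.read_csv(fh)
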