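"""Parametric marginal distributions for pollutant concentrations.

Hourly concentration marginals are positive and right-skewed; five
two-parameter families cover the shapes seen in practice: Weibull,
Gamma, Lognormal, Log-logistic and Inverse Gaussian.  Parameters are
named (a, b) per family as (scale-like, shape-like):

=============  =====================  ==========================
family         a                      b
=============  =====================  ==========================
weibull        scale                  shape
gamma          shape                  scale
lognormal      sigma of log(X)        mu of log(X) (any sign)
loglogistic    shape                  scale
invgauss       mean mu                shape lambda
=============  =====================  ==========================

Rather than maximum likelihood, fitting maximizes the goodness of fit
R^2 between the empirical CDF (median-unbiased plotting positions
i/(n+1) at the sorted sample) and the model CDF, searched with the
BBODE optimizer — robust for the heavy-tailed, rounded data that air
monitors produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gamma as gamma_fn

from aerowarn.bbode import BBODEConfig, bbo_iteration, de_iteration, _evaluate

FAMILIES = ("weibull", "gamma", "lognormal", "loglogistic", "invgauss")


def _frozen(family: str, a: float, b: float):
    if family == "weibull":
        if a <= 0 or b <= 0:
            raise ValueError("weibull requires a, b > 0")
        return stats.weibull_min(c=b, scale=a)
    if family == "gamma":
        if a <= 0 or b <= 0:
            raise ValueError("gamma requires a, b > 0")
        return stats.gamma(a, scale=b)
    if family == "lognormal":
        if a <= 0:
            raise ValueError("lognormal requires sigma a > 0")
        return stats.lognorm(s=a, scale=np.exp(b))
    if family == "loglogistic":
        if a <= 0 or b <= 0:
            raise ValueError("loglogistic requires a, b > 0")
        return stats.fisk(c=a, scale=b)
    if family == "invgauss":
        if a <= 0 or b <= 0:
            raise ValueError("invgauss requires a, b > 0")
        return stats.invgauss(mu=a / b, scale=b)
    raise ValueError(f"unknown family {family!r}")


def pdf(family: str, a: float, b: float, x):
    """Density of the family at ``x`` (x >= 0; > 0 for log families)."""
    return _frozen(family, a, b).pdf(x)


def cdf(family: str, a: float, b: float, x):
    """Cumulative probability of the family at ``x``."""
    return _frozen(family, a, b).cdf(x)


@dataclass
class DistributionFit:
    family: str
    a: float
    b: float
    r_squared: float


def _moment_start(family: str, data: np.ndarray) -> tuple[float, float]:
    """Crude moment-matched parameters used to seed the search."""
    m, v = float(np.mean(data)), float(np.var(data))
    v = max(v, 1e-12)
    if family == "weibull":
        cv = np.sqrt(v) / m
        b = max(cv**-1.086, 0.1)  # standard CV-based shape approximation
        a = m / float(gamma_fn(1 + 1 / b))
        return a, b
    if family == "gamma":
        shape = m * m / v
        return shape, v / m
    if family == "lognormal":
        s2 = np.log(1 + v / m**2)
        return float(np.sqrt(s2)), float(np.log(m) - s2 / 2)
    if family == "loglogistic":
        s2 = np.log(1 + v / m**2)
        sigma = np.sqrt(s2)
        return float(np.pi / (np.sqrt(3) * sigma)), float(np.exp(np.log(m) - s2 / 2))
    if family == "invgauss":
        return m, m**3 / v
    raise ValueError(f"unknown family {family!r}")


def r_squared_cdf(family: str, a: float, b: float, data_sorted: np.ndarray, ecdf: np.ndarray) -> float:
    """R^2 between empirical and model CDF at the sorted sample."""
    try:
        with np.errstate(over="ignore", under="ignore"):
            est = cdf(family, a, b, data_sorted)
    except ValueError:
        return -np.inf
    ss_res = float(np.sum((ecdf - est) ** 2))
    ss_tot = float(np.sum((ecdf - ecdf.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def _search_box(family: str, data: np.ndarray) -> np.ndarray:
    """Log10 search box for (a, b); lognormal mu is searched linearly."""
    if family == "lognormal":
        return np.array([[-3.0, 1.0], [-5.0, 10.0]])  # log10 sigma, raw mu
    return np.array([[-3.0, 4.0], [-3.0, 4.0]])


def _decode(family: str, theta: np.ndarray) -> tuple[float, float]:
    if family == "lognormal":
        return 10.0 ** theta[0], float(theta[1])
    return 10.0 ** theta[0], 10.0 ** theta[1]


def _encode(family: str, a: float, b: float) -> np.ndarray:
    if family == "lognormal":
        return np.array([np.log10(a), b])
    return np.array([np.log10(max(a, 1e-3)), np.log10(max(b, 1e-3))])


def fit_distribution(
    data,
    family: str,
    optimizer_config: BBODEConfig | None = None,
) -> DistributionFit:
    """Fit one family by maximizing CDF goodness of fit R^2 with BBODE.

    Requires a positive sample of size >= 30.  The initial population
    is seeded with moment-matched parameters, so the fitted R^2 is
    never below the moment-matched one.
    """
    data = np.asarray(data, dtype=float).ravel()
    if len(data) < 30:
        raise ValueError("need a sample of size >= 30")
    if np.any(data <= 0):
        raise ValueError("sample values must be positive")
    if np.ptp(data) == 0:
        raise ValueError("degenerate all-equal sample")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")

    xs = np.sort(data)
    n = len(xs)
    ecdf = np.arange(1, n + 1) / (n + 1.0)

    def objective(theta):
        theta = np.atleast_2d(theta)
        out = np.empty(len(theta))
        for i, t in enumerate(theta):
            a, b = _decode(family, t)
            out[i] = -r_squared_cdf(family, a, b, xs, ecdf)
        return out

    cfg = optimizer_config or BBODEConfig(pop_size=30, max_iter=200, seed=0)
    box = _search_box(family, data)
    lo, hi = box[:, 0], box[:, 1]

    rng = np.random.default_rng(cfg.seed)
    X = rng.uniform(lo, hi, (cfg.pop_size, 2))
    try:
        X[0] = np.clip(_encode(family, *_moment_start(family, data)), lo, hi)
    except Exception:
        pass
    fitv = _evaluate(objective, X, True)
    for g in range(1, cfg.max_iter + 1):
        X, fitv = bbo_iteration(X, fitv, lo, hi, cfg, rng, objective, True)
        if cfg.use_de and g % 2 == 0:
            X, fitv = de_iteration(
                X, fitv, lo, hi, cfg.de_factor, cfg.de_crossover, rng, objective, True
            )
    best = X[np.argmin(fitv)]
    a, b = _decode(family, best)
    return DistributionFit(family, a, b, -float(fitv.min()))


def fit_all(data, optimizer_config: BBODEConfig | None = None) -> dict[str, DistributionFit]:
    """Fit every family and return a name -> fit mapping."""
    return {fam: fit_distribution(data, fam, optimizer_config) for fam in FAMILIES}
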