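"""Normal/half cloud-model multi-criteria air-quality evaluation.

A cloud model represents a qualitative grade ("air quality level II")
by a random membership function with three parameters: expectation Ex
(the grade's typical concentration), entropy En (the span of
concentrations the grade accepts) and hyper-entropy He (the run-to-run
variability of the membership itself).  From a criterion's level
boundaries (B_min, B_max]:

    Ex = (B_max + B_min) / 2,   En = (B_max - B_min) / 3,   He = k En

with atomization k = 0.1.  The worst level has no printed upper bound;
a quadratic regression through the five lower upper-bounds,
extrapolated to level index 6, supplies the pseudo-bound.

Evaluating an observation x against a grade uses the X-condition cloud
generator: draw En' ~ Normal(En, He^2) (redraw on En' <= 0) and emit
mu = exp(-(x - Ex)^2 / (2 En'^2)).  The extreme grades use *half*
clouds — membership is 1 on the closed side of Ex (below Ex at the
best level, above Ex at the worst level) and Gaussian-decaying on the
open side.

A six-pollutant sample aggregates per-criterion certainties with
entropy-AHP weights, U = sum_i W_i mu_i; repeating the draw (2000
times by default) and averaging gives the final certainty degree per
level, and the level with the maximum mean certainty is the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from aerowarn.synthetic import CRITERIA, LEVELS, load_fixture


@dataclass(frozen=True)
class CloudEntry:
    """Cloud parameters of one criterion x level cell."""

    Ex: float
    En: float
    He: float
    half_side: str | None = None  # None | "lower" (best level) | "upper" (worst)


class CloudSpec:
    """(Ex, En, He) per criterion x level, with half-cloud flags at I/VI."""

    def __init__(self, table: pd.DataFrame, k: float = 0.1):
        self.k = k
        self._entries: dict[tuple[str, str], CloudEntry] = {}
        for _, row in table.iterrows():
            lvl = row["level"]
            half = "lower" if lvl == LEVELS[0] else ("upper" if lvl == LEVELS[-1] else None)
            self._entries[(row["criterion"], lvl)] = CloudEntry(
                float(row["Ex"]), float(row["En"]), float(row["He"]), half
            )

    def __getitem__(self, key: tuple[str, str]) -> CloudEntry:
        return self._entries[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"criterion": c, "level": l, "Ex": e.Ex, "En": e.En, "He": e.He}
            for (c, l), e in self._entries.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_fixture(cls, k: float = 0.1) -> "CloudSpec":
        """The worked-example cloud parameter table, as printed."""
        return cls(load_fixture("cloud_params"), k)


def pseudo_bound(upper_bounds) -> float:
    """Extrapolated upper bound of the open-ended worst level.

    Ordinary least-squares quadratic through (level index i, bound_i)
    for i = 1..len(bounds), evaluated at the next index.  With exactly
    collinear inputs the quadratic coefficient vanishes and the linear
    extrapolation is returned.
    """
    y = np.asarray(upper_bounds, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 boundary points")
    if np.any(y <= 0) or np.any(np.diff(y) <= 0):
        raise ValueError("bounds must be positive and strictly increasing")
    x = np.arange(1, len(y) + 1, dtype=float)
    coef = np.polyfit(x, y, 2)
    return float(np.polyval(coef, len(y) + 1.0))


def criteria_bounds(with_pseudo: bool = True, exact_ols: bool = False) -> pd.DataFrame:
    """Level bounds (B_min, B_max] per criterion.

    Level I starts at 0 and each level's lower bound is the previous
    upper bound.  The worst level's upper bound is the pseudo-bound:
    by default the printed regression values shipped as a fixture,
    or the exact OLS extrapolation with ``exact_ols=True``.
    """
    upper = load_fixture("criteria_bounds").set_index("level")
    pseudo = load_fixture("pseudo_bounds").set_index("criterion")["bmax_vi"]
    rows = []
    for crit in CRITERIA:
        bmaxes = [float(upper.loc[lvl, crit]) for lvl in LEVELS[:-1]]
        vi = pseudo_bound(bmaxes) if exact_ols else float(pseudo[crit])
        bmaxes.append(vi)
        bmin = 0.0
        for lvl, bmax in zip(LEVELS, bmaxes):
            rows.append({"criterion": crit, "level": lvl, "bmin": bmin, "bmax": bmax})
            bmin = bmax
    return pd.DataFrame(rows)


def cloud_params(bounds: pd.DataFrame, k: float = 0.1) -> CloudSpec:
    """Cloud parameters from level bounds: Ex midpoint, En span/3, He = k En."""
    rows = []
    for _, r in bounds.iterrows():
        bmin, bmax = float(r["bmin"]), float(r["bmax"])
        if bmax <= bmin:
            raise ValueError(f"B_max <= B_min for {r['criterion']} {r['level']}")
        en = (bmax - bmin) / 3.0
        rows.append(
            {
                "criterion": r["criterion"],
                "level": r["level"],
                "Ex": (bmax + bmin) / 2.0,
                "En": en,
                "He": k * en,
            }
        )
    return CloudSpec(pd.DataFrame(rows), k)


def entropy_weights(samples: dict[str, np.ndarray], n_bins: int = 10) -> np.ndarray:
    """Data-driven criterion weights from histogram entropy.

    For each criterion, relative frequencies F_t over ``n_bins``
    equal-width bins spanning its observed range give the entropy
    e = -sum F_t ln F_t (0 ln 0 = 0), normalized to E = e / ln T; the
    weight of criterion i is (1 - E_i) / (C - sum E) and the weights
    sum to one.  A constant sample has zero entropy (most
    informative).  When all criteria are maximally entropic the
    formula degenerates to 0/0 and equal weights 1/C are returned.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    names = list(samples)
    C = len(names)
    E = np.empty(C)
    for i, name in enumerate(names):
        x = np.asarray(samples[name], dtype=float).ravel()
        if len(x) == 0:
            raise ValueError(f"empty sample for {name}")
        if np.ptp(x) == 0:
            E[i] = 0.0  # constant: zero uncertainty
            continue
        counts, _ = np.histogram(x, bins=n_bins)
        F = counts / counts.sum()
        F = F[F > 0]
        e = -float(np.sum(F * np.log(F)))
        E[i] = e / np.log(n_bins)
    denom = C - float(E.sum())
    if denom <= 1e-12:
        return np.full(C, 1.0 / C)
    w = (1.0 - E) / denom
    return w


def combine_weights(z, omega) -> np.ndarray:
    """Entropy-AHP weights W_i proportional to z_i * omega_i, summing to 1."""
    z = np.asarray(z, dtype=float).ravel()
    omega = np.asarray(omega, dtype=float).ravel()
    if len(z) != len(omega):
        raise ValueError("z and omega must have equal length")
    if np.any(z < 0) or np.any(omega < 0):
        raise ValueError("weights must be non-negative")
    prod = z * omega
    s = prod.sum()
    if s == 0:
        raise ValueError("all weight products are zero")
    return prod / s


def certainty(
    x: float,
    cloud: CloudEntry,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """X-condition certainty degrees of observation ``x`` in one cloud.

    Draws En' ~ Normal(En, He^2), rejecting non-positive draws, and
    returns mu = exp(-(x - Ex)^2 / (2 En'^2)) for each repetition.
    Half clouds return 1 on their closed side of Ex.
    """
    if cloud.half_side == "lower" and x <= cloud.Ex:
        return np.ones(size)
    if cloud.half_side == "upper" and x >= cloud.Ex:
        return np.ones(size)
    if cloud.He == 0:
        en = np.full(size, cloud.En)
    else:
        en = rng.normal(cloud.En, cloud.He, size)
        bad = en <= 0
        while bad.any():
            en[bad] = rng.normal(cloud.En, cloud.He, int(bad.sum()))
            bad = en <= 0
    return np.exp(-((x - cloud.Ex) ** 2) / (2.0 * en**2))


@dataclass
class EvaluationResult:
    """Mean certainty degree per level and the argmax level."""

    certainty: dict[str, float]
    final_level: str
    reps: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.certainty)


def evaluate(
    sample: dict[str, float],
    clouds: CloudSpec,
    weights,
    reps: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> EvaluationResult:
    """Grade one six-pollutant sample against every level's clouds.

    For each level, U = mean over ``reps`` repetitions of
    sum_i W_i mu_i; the verdict is the level with maximal U, ties
    broken toward the worse (higher) level.
    """
    missing = [c for c in CRITERIA if c not in sample]
    if missing:
        raise ValueError(f"sample missing criteria: {missing}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    W = np.asarray(weights, dtype=float).ravel()
    if len(W) != len(CRITERIA):
        raise ValueError("need one weight per criterion")

    U = {}
    for lvl in LEVELS:
        total = np.zeros(reps)
        for w, crit in zip(W, CRITERIA):
            total += w * certainty(float(sample[crit]), clouds[(crit, lvl)], rng, reps)
        U[lvl] = float(total.mean())
    # argmax with ties resolved toward the worse level
    best = max(range(len(LEVELS)), key=lambda i: (U[LEVELS[i]], i))
    return EvaluationResult(U, LEVELS[best], reps)


def default_weights() -> np.ndarray:
    """The worked-example entropy-AHP weight vector W, as printed."""
    tab = load_fixture("weights").set_index("criterion")
    return tab.loc[list(CRITERIA), "W"].to_numpy(dtype=float)
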