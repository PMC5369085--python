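"""Biogeography-based optimization hybridized with differential evolution.

BBO treats each candidate solution as an island habitat whose fitness
(habitat suitability index, lower is better here) maps to a species
rank k.  Rich habitats emigrate decision-variable values; poor habitats
immigrate them, with rank-dependent rates lambda_k (immigration) and
mu_k (emigration) given by one of four migration models (cosine,
quadratic, exponential, linear).  BBO explores well but exploits
poorly, so the hybrid (BBODE) additionally applies one
DE/rand/1/bin step with greedy selection on every even-numbered
generation, which sharpens local search without losing BBO's global
information sharing.

The module also carries the standard benchmark suite (sphere,
rosenbrock, rastrigin, griewank, ackley, schaffer) on their canonical
box domains, used both for validating the optimizer and as ready-made
objectives for the command-line interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

MIGRATION_MODELS = ("cosine", "quadratic", "exponential", "linear")


@dataclass(frozen=True)
class MigrationModel:
    """Functional form mapping species rank k to (lambda_k, mu_k)."""

    name: str = "cosine"
    I: float = 1.0
    E: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in MIGRATION_MODELS:
            raise ValueError(f"unknown migration model {self.name!r}")
        if not (0 < self.I <= 1) or not (0 < self.E <= 1):
            raise ValueError("I and E must lie in (0, 1]")


def migration_rates(k, n: int, model: MigrationModel | str = "cosine"):
    """Immigration and emigration rates for rank ``k`` of ``n`` species.

    ``k`` may be a scalar or array in [0, n].  k = 0 is the emptiest
    (worst) habitat: maximal immigration, zero emigration; k = n is the
    fullest (best): zero immigration, maximal emigration.
    """
    if isinstance(model, str):
        model = MigrationModel(model)
    k = np.asarray(k, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("rank k must lie in [0, n]")
    r = k / n
    if model.name == "cosine":
        lam = 0.5 * model.I * (1 + np.cos(r * np.pi))
        mu = 0.5 * model.E * (1 - np.cos(r * np.pi))
    elif model.name == "quadratic":
        lam = model.I * (r - 1) ** 2
        mu = model.E * r**2
    elif model.name == "exponential":
        lam = model.I * np.exp(-r)
        mu = model.E * np.exp(r - 1)
    else:  # linear
        lam = model.I * (1 - r)
        mu = model.E * r
    return lam, mu


@dataclass(frozen=True)
class BBODEConfig:
    """Optimizer settings.

    Defaults are the hybrid's reference configuration: population 50,
    5000 generations, 3 elites, mutation probability 0.4, difference
    factor F = 0.6 and cosine migration.  Plain BBO uses
    ``use_de=False`` and mutation probability 0.05.
    """

    pop_size: int = 50
    max_iter: int = 5000
    n_elites: int = 3
    mutation_prob: float = 0.4
    de_factor: float = 0.6
    de_crossover: float = 0.9
    migration: str = "cosine"
    I: float = 1.0
    E: float = 1.0
    use_de: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pop_size > self.n_elites >= 0:
            raise ValueError("require pop_size > n_elites >= 0")
        if not 0 <= self.mutation_prob <= 1:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.use_de and self.pop_size < 4:
            raise ValueError("DE requires pop_size >= 4")

    @classmethod
    def bbo(cls, **kw) -> "BBODEConfig":
        """Plain-BBO preset (no DE step, mutation probability 0.05)."""
        kw.setdefault("use_de", False)
        kw.setdefault("mutation_prob", 0.05)
        return cls(**kw)


def _evaluate(objective: Callable, X: np.ndarray, vectorized: bool) -> np.ndarray:
    if vectorized:
        f = np.asarray(objective(X), dtype=float)
    else:
        f = np.array([objective(x) for x in X], dtype=float)
    # non-finite objective values are treated as worst possible
    f[~np.isfinite(f)] = np.inf
    return f


def bbo_iteration(
    X: np.ndarray,
    fit: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    config: BBODEConfig,
    rng: np.random.Generator,
    objective: Callable,
    vectorized: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One BBO generation: migration, mutation, elitism.

    ``X``/``fit`` need not be sorted.  Ranking maps the best habitat to
    k = n (lowest immigration, highest emigration) and the worst to
    k = 0.  Each decision variable of each habitat immigrates with
    probability lambda_k, receiving the value of an emigrating habitat
    drawn by roulette over the mu rates (the habitat itself excluded).
    Mutation then picks each habitat with probability
    ``mutation_prob`` and redraws one uniformly chosen variable
    uniformly in the bounds.  Finally the previous generation's elites
    replace the worst of the new one, so the best fitness never
    worsens.
    """
    P, D = X.shape
    order = np.argsort(fit, kind="stable")
    X = X[order]
    fit = fit[order]
    elites = config.n_elites
    elite_X = X[:elites].copy()
    elite_f = fit[:elites].copy()

    n = P
    k = n - np.arange(P)  # best habitat holds the most species
    lam, mu = migration_rates(k, n, MigrationModel(config.migration, config.I, config.E))

    immigrate = rng.random((P, D)) < lam[:, None]
    newX = X.copy()
    if immigrate.any():
        MU = np.tile(mu, (P, 1))
        MU[np.arange(P), np.arange(P)] = 0.0  # no self-emigration
        cum = np.cumsum(MU, axis=1)
        r = rng.random((P, D)) * cum[:, -1:]
        src = (r[:, :, None] >= cum[:, None, :]).sum(axis=2)
        rows, cols = np.where(immigrate)
        newX[rows, cols] = X[src[rows, cols], cols]

    if config.mutation_prob > 0:
        mutate = rng.random(P) < config.mutation_prob
        var = rng.integers(0, D, P)
        draws = rng.uniform(lo, hi, (P, D))
        idx = np.where(mutate)[0]
        newX[idx, var[idx]] = draws[idx, var[idx]]

    np.clip(newX, lo, hi, out=newX)
    newfit = _evaluate(objective, newX, vectorized)

    if elites:
        worst = np.argsort(newfit, kind="stable")[-elites:]
        newX[worst] = elite_X
        newfit[worst] = elite_f
    return newX, newfit


def de_iteration(
    X: np.ndarray,
    fit: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    F: float,
    CR: float,
    rng: np.random.Generator,
    objective: Callable,
    vectorized: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One DE/rand/1/bin generation with greedy selection.

    Trials ``x_r1 + F (x_r2 - x_r3)`` (distinct random indices, all
    different from the target) undergo binomial crossover at rate
    ``CR`` and replace their target only on strict improvement, so the
    population's mean fitness never increases.
    """
    P, D = X.shape
    if P < 4:
        raise ValueError("DE requires a population of at least 4")

    # three mutually distinct donors, none equal to the target
    idx = np.arange(P)
    donors = np.empty((P, 3), dtype=int)
    for j in range(3):
        donors[:, j] = rng.integers(0, P, P)
    bad = (
        (donors[:, 0] == idx)
        | (donors[:, 1] == idx)
        | (donors[:, 2] == idx)
        | (donors[:, 0] == donors[:, 1])
        | (donors[:, 0] == donors[:, 2])
        | (donors[:, 1] == donors[:, 2])
    )
    while bad.any():
        donors[bad] = rng.integers(0, P, (int(bad.sum()), 3))
        bad = (
            (donors[:, 0] == idx)
            | (donors[:, 1] == idx)
            | (donors[:, 2] == idx)
            | (donors[:, 0] == donors[:, 1])
            | (donors[:, 0] == donors[:, 2])
            | (donors[:, 1] == donors[:, 2])
        )

    trial = X[donors[:, 0]] + F * (X[donors[:, 1]] - X[donors[:, 2]])
    cross = rng.random((P, D)) < CR
    cross[np.arange(P), rng.integers(0, D, P)] = True  # at least one gene
    trial = np.where(cross, trial, X)
    np.clip(trial, lo, hi, out=trial)

    tfit = _evaluate(objective, trial, vectorized)
    better = tfit < fit
    X = X.copy()
    fit = fit.copy()
    X[better] = trial[better]
    fit[better] = tfit[better]
    return X, fit


def optimize(
    objective: Callable,
    bounds,
    dim: int | None = None,
    config: BBODEConfig | None = None,
    vectorized: bool = False,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize ``objective`` over a box with BBODE (or plain BBO).

    ``bounds`` is either ``(lo, hi)`` scalars with ``dim`` given, or a
    sequence of per-dimension ``(lo, hi)`` pairs.  Every generation
    runs one BBO iteration; even-numbered generations additionally run
    one DE iteration when ``config.use_de``.  Returns the best
    solution, its fitness, and the best-fitness history per
    generation.  Deterministic given ``config.seed``.
    """
    cfg = config or BBODEConfig()
    b = np.asarray(bounds, dtype=float)
    if b.ndim == 1:
        if dim is None:
            raise ValueError("dim required with scalar bounds")
        lo = np.full(dim, b[0])
        hi = np.full(dim, b[1])
    else:
        lo, hi = b[:, 0], b[:, 1]
    if np.any(hi <= lo):
        raise ValueError("upper bounds must exceed lower bounds")
    D = len(lo)

    rng = np.random.default_rng(cfg.seed)
    X = rng.uniform(lo, hi, (cfg.pop_size, D))
    fit = _evaluate(objective, X, vectorized)

    history = np.empty(cfg.max_iter)
    for g in range(1, cfg.max_iter + 1):
        X, fit = bbo_iteration(X, fit, lo, hi, cfg, rng, objective, vectorized)
        if cfg.use_de and g % 2 == 0:
            X, fit = de_iteration(
                X, fit, lo, hi, cfg.de_factor, cfg.de_crossover, rng, objective, vectorized
            )
        history[g - 1] = fit.min()

    best = int(np.argmin(fit))
    return X[best].copy(), float(fit[best]), history


# ---------------------------------------------------------------------------
# benchmark functions (vectorized over rows of a (P, D) matrix)

def sphere(X):
    X = np.atleast_2d(X)
    return np.sum(X**2, axis=1)


def rosenbrock(X):
    X = np.atleast_2d(X)
    return np.sum(100.0 * (X[:, 1:] - X[:, :-1] ** 2) ** 2 + (1 - X[:, :-1]) ** 2, axis=1)


def rastrigin(X):
    X = np.atleast_2d(X)
    return np.sum(X**2 - 10 * np.cos(2 * np.pi * X) + 10, axis=1)


def griewank(X):
    X = np.atleast_2d(X)
    d = X.shape[1]
    j = np.sqrt(np.arange(1, d + 1))
    return 1 + np.sum(X**2, axis=1) / 4000.0 - np.prod(np.cos(X / j), axis=1)


def ackley(X):
    X = np.atleast_2d(X)
    d = X.shape[1]
    s1 = np.sum(X**2, axis=1) / d
    s2 = np.sum(np.cos(2 * np.pi * X), axis=1) / d
    return -20 * np.exp(-0.2 * np.sqrt(s1)) - np.exp(s2) + 20 + np.e


def schaffer(X):
    """Schaffer F6, summed over consecutive coordinate pairs for D > 2."""
    X = np.atleast_2d(X)
    a = X[:, :-1] ** 2 + X[:, 1:] ** 2
    terms = 0.5 + (np.sin(np.sqrt(a)) ** 2 - 0.5) / (1 + 0.001 * a) ** 2
    return np.sum(terms, axis=1)


#: Benchmark name -> (function, canonical box domain).
BENCHMARKS = {
    "sphere": (sphere, (-30.0, 30.0)),
    "rosenbrock": (rosenbrock, (-30.0, 30.0)),
    "rastrigin": (rastrigin, (-5.12, 5.12)),
    "griewank": (griewank, (-600.0, 600.0)),
    "ackley": (ackley, (-32.0, 32.0)),
    "schaffer": (schaffer, (-100.0, 100.0)),
}


def benchmark_runs(
    name: str,
    dim: int,
    n_runs: int = 20,
    config: BBODEConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Best objective value from ``n_runs`` independent seeded runs."""
    f, box = BENCHMARKS[name]
    cfg = config or BBODEConfig()
    out = np.empty(n_runs)
    for r in range(n_runs):
        run_cfg = BBODEConfig(**{**cfg.__dict__, "seed": seed + r})
        _, best, _ = optimize(f, box, dim=dim, config=run_cfg, vectorized=True)
        out[r] = best
    return out
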