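"""End-to-end early-warning orchestration.

One call runs the whole system for a set of pollutant series:
decompose (CEEMD), drop the noise mode, split, tune and fit the LSSVM,
emit point forecasts and prediction intervals per criterion, then feed
the per-timestamp forecast vectors to the cloud evaluator to produce
air-quality levels with certainty degrees.  Every stochastic stage
draws from a child stream of the global seed, so reports are
reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from aerowarn import __version__
from aerowarn.bbode import BBODEConfig
from aerowarn.ceemd import CEEMDConfig
from aerowarn.cloudeval import CloudSpec, default_weights, evaluate
from aerowarn.interval import predict_interval, score_intervals
from aerowarn.lssvm import ForecastTask, forecast_pipeline
from aerowarn.metrics import point_metrics
from aerowarn.synthetic import CRITERIA, PollutantSeries, SyntheticSpec, generate_series

log = logging.getLogger("aerowarn")


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_ews`."""

    criteria: tuple[str, ...] = CRITERIA
    lag_order: int = 5
    split_fraction: float = 0.8
    significance_levels: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4)
    ceemd: CEEMDConfig = field(default_factory=lambda: CEEMDConfig(ensemble_size=20))
    bbode: BBODEConfig = field(default_factory=lambda: BBODEConfig(pop_size=20, max_iter=40))
    cloud_k: float = 0.1
    eval_reps: int = 2000
    evaluate_actuals: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [c for c in self.criteria if c not in CRITERIA]
        if unknown:
            raise ValueError(f"unknown criteria {unknown}")
        if not all(0 < a < 1 for a in self.significance_levels):
            raise ValueError("significance levels must lie in (0, 1)")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "ceemd" in raw:
            raw["ceemd"] = CEEMDConfig(**raw["ceemd"])
        if "bbode" in raw:
            raw["bbode"] = BBODEConfig(**raw["bbode"])
        for key in ("criteria", "significance_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_ews(
    config: PipelineConfig,
    series: dict[str, PollutantSeries] | None = None,
    out_dir=None,
) -> dict:
    """Run forecasting + intervals + cloud evaluation for all criteria.

    ``series`` maps criterion names to input series; missing criteria
    are filled with synthetic series (seeded from the global seed).
    Returns the report as a dict; when ``out_dir`` is given, also
    writes per-criterion prediction CSVs and the JSON report there.
    """
    root_ss = np.random.SeedSequence(config.seed)
    crit_seeds = {c: s for c, s in zip(config.criteria, root_ss.spawn(len(config.criteria)))}
    eval_ss = root_ss.spawn(1)[0]
    series = dict(series or {})
    log.info("run_ews start: config %s", config.digest())

    forecasts: dict[str, pd.DataFrame] = {}
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "criteria": {},
    }
    for crit in config.criteria:
        ss = crit_seeds[crit]
        if crit not in series:
            series[crit] = generate_series(
                SyntheticSpec(seed=_child_seed(ss)), criterion=crit
            )
        s = series[crit]
        task = ForecastTask(s, config.lag_order, int(config.split_fraction * len(s)))
        cc = CEEMDConfig(**{**config.ceemd.__dict__, "seed": _child_seed(ss)})
        bc = BBODEConfig(**{**config.bbode.__dict__, "seed": _child_seed(ss)})
        try:
            res = forecast_pipeline(task, cc, bc)
        except RuntimeError as exc:
            raise RuntimeError(f"[{crit}] {exc}") from exc
        df = pd.DataFrame(
            {"timestamp": res.timestamps, "actual": res.actual, "predicted": res.predicted}
        )
        # interval columns per requested significance level
        split = task.split_index - task.lag_order
        X_all, y_all = _lag(res.denoised, task.lag_order)
        sc = res.standardizer
        for a in config.significance_levels:
            ivs = predict_interval(
                res.model, sc.fx(X_all[split:]), a, sc.fy(y_all[:split])
            )
            df[f"lower_{a}"] = [sc.inv_y(iv.lower) for iv in ivs]
            df[f"upper_{a}"] = [sc.inv_y(iv.upper) for iv in ivs]
        forecasts[crit] = df

        m = point_metrics(res.actual, res.predicted)
        report["criteria"][crit] = {
            "sigma": res.sigma,
            "gamma": res.gamma,
            "n_test": int(len(res.actual)),
            "mae": m.mae,
            "mape": m.mape,
            "rmse": m.rmse,
            "r2": m.r2,
        }
        log.info("[%s] forecast done: MAE %.3f", crit, m.mae)

    report["evaluation"] = evaluate_forecasts(
        forecasts,
        reps=config.eval_reps,
        seed=_child_seed(eval_ss),
        use_actuals=config.evaluate_actuals,
        k=config.cloud_k,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for crit, df in forecasts.items():
            df.to_csv(out / f"predictions_{crit.replace('.', '')}.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _lag(values, d):
    from aerowarn.lssvm import make_lag_matrix

    return make_lag_matrix(values, d)


def evaluate_forecasts(
    forecasts: dict[str, pd.DataFrame],
    reps: int = 2000,
    seed: int = 0,
    use_actuals: bool = False,
    k: float = 0.1,
) -> list[dict]:
    """Cloud-evaluate the per-timestamp forecast vectors.

    Uses the printed cloud parameters and entropy-AHP weights; one
    record per timestamp present in every criterion's forecast frame.
    """
    clouds = CloudSpec.from_fixture(k)
    W = default_weights()
    col = "actual" if use_actuals else "predicted"
    crits = list(forecasts)
    common = None
    for df in forecasts.values():
        stamps = pd.DatetimeIndex(df["timestamp"])
        common = stamps if common is None else common.intersection(stamps)
    rng = np.random.default_rng(seed)
    records = []
    for ts in common:
        sample = {
            c: float(
                forecasts[c].loc[pd.DatetimeIndex(forecasts[c]["timestamp"]) == ts, col].iloc[0]
            )
            for c in crits
        }
        for c in CRITERIA:  # criteria not forecast default to tiny clean values
            sample.setdefault(c, 0.0)
        res = evaluate(sample, clouds, W, reps=reps, rng=rng)
        records.append(
            {"timestamp": str(ts), "certainty": res.certainty, "level": res.final_level}
        )
    return records
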