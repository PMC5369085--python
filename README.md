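# aerowarn

An air-quality early-warning toolkit for public-health forecasting:
point and interval forecasts of six hourly pollutant concentrations
(PM2.5, PM10, O3, CO, NO2, SO2) and a multi-criteria evaluator that
converts a forecast vector into an air-quality level (I–VI) with a
certainty degree. It is aimed at environmental-health analysts who
need both a numeric forecast *and* a defensible qualitative verdict
("tomorrow 09:00 is level II, with certainty 0.61").

## The method

**Forecasting.** Raw monitor series are noisy and nonstationary, so a
hybrid pipeline is used:

1. **CEEMD** — complementary ensemble empirical mode decomposition
   splits the series f(t) into intrinsic mode functions,
   f(t) = Σⱼ IMFⱼ(t) + rₙ(t), by sifting the signal perturbed with
   paired ± white-noise realizations and averaging; the pairs cancel,
   so the decomposition still reconstructs f exactly. The
   highest-frequency mode IMF₁ carries mostly measurement noise and is
   removed before modeling.
2. **LSSVM** — least-squares support vector regression with RBF kernel
   K(xᵢ,xⱼ) = exp(−‖xᵢ−xⱼ‖²/2σ²) on a 5-lag embedding; fitting is a
   single bordered linear solve for the dual coefficients (b, α).
3. **BBODE** — a biogeography-based optimizer (cosine migration model,
   rank-dependent immigration/emigration rates λₖ, μₖ) hybridized with
   a DE/rand/1/bin step on even generations; it searches (σ, γ) by
   minimizing holdout MSE, and also drives the distribution-fitting
   module.
4. **Intervals** — the fitted LSSVM is a linear smoother (ŷ = L y), so
   pointwise prediction intervals follow from double-smoothing bias
   correction and smoothed-residual variance estimation:
   (ŷ − bias) ± z_{a/2}·√var. Coverage probability (CP) and average
   width (AW) score them; intervals are valid when CP ≥ 1 − a.

**Evaluation.** Each pollutant × level interval (B_min, B_max] becomes
a normal cloud Ex = (B_max+B_min)/2, En = (B_max−B_min)/3, He = 0.1·En
(half clouds at the extreme levels; the open-ended level VI bound is
extrapolated by quadratic regression). An observation x gets the
random membership μ = exp(−(x−Ex)²/2En′²) with En′ ~ N(En, He²);
entropy-AHP weights combine the six criteria, U = Σᵢ Wᵢ μᵢ, and the
mean of U over 2000 repetitions per level picks the final level by
argmax.

## Worked example

The nine reference forecast vectors shipped with the package can be
graded directly:

```python
import numpy as np
from aerowarn import CRITERIA, load_fixture
from aerowarn.cloudeval import CloudSpec, default_weights, evaluate

clouds = CloudSpec.from_fixture()
W = default_weights()
samples = load_fixture("eval_samples").set_index("case")
s = {c: float(samples.loc["A_3", c]) for c in CRITERIA}
res = evaluate(s, clouds, W, reps=2000, rng=5)
print(res.final_level, round(res.certainty["I"], 4))
```

prints

```
I 0.9119
```

— sample A_3 (a clean morning: PM2.5 = 8.4 µg/m³) is graded level I
("excellent") with certainty 0.9119; the certainty is the weighted,
Monte-Carlo-averaged membership of all six pollutants in the level-I
clouds. A full synthetic end-to-end run (forecast + intervals +
evaluation) is one call:

```bash
aerowarn run --seed 1 --out aerowarn_out
```

which writes per-pollutant `predictions_*.csv` (actual, predicted,
interval bounds per significance level) and `report.json` with MAE /
MAPE / RMSE / R² per pollutant and a per-timestamp level verdict.

## Layout

- `aerowarn.synthetic` — synthetic hourly series generator + bundled tables
- `aerowarn.ceemd` — EMD / CEEMD / IMF₁-removal denoiser
- `aerowarn.bbode` — BBO, DE hybrid, migration models, benchmark suite
- `aerowarn.lssvm` — LSSVM dual solve, tuning, forecasting pipeline
- `aerowarn.interval` — smoother matrix, bias/variance, intervals, CP/AW
- `aerowarn.distfit` — five positive families fitted by CDF R² with BBODE
- `aerowarn.cloudeval` — clouds, pseudo-bounds, entropy-AHP weights, evaluator
- `aerowarn.metrics` — MAE/MAPE/RMSE/R² and the Diebold–Mariano test
- `aerowarn.pipeline`, `aerowarn.cli` — orchestration and the `aerowarn` CLI

See `docs/methods.md` for modeling assumptions, parameter choices and
known limitations.
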