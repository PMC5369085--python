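# Methods

This note records the models implemented in `aerowarn`, the choices
made where the design was genuinely open, and what the test suite does
and does not demonstrate.

## Synthetic pollutant series

Real hourly pollutant series are positive, right-skewed, strongly
autocorrelated, diurnal, and occasionally spiky. The generator models

    value_t = baseline + A·sin(2πt/24) + AR(1) noise + spikes,  clipped at 0

with defaults baseline 40 µg/m³, diurnal amplitude 8 µg/m³, AR(1)
coefficient 0.8, marginal noise SD 10 µg/m³, spike rate 0.01/hour with
exponential magnitude (mean 30 µg/m³). These are typical of a
moderately polluted coastal city and give visibly pollutant-like
traces. The AR(1) innovations are scaled so the *marginal* SD equals
`noise_scale`; the lag-1 autocorrelation of the sum then tracks the
AR coefficient to within ±0.1 for series of a few thousand hours.

What the generator does **not** emulate: cross-pollutant correlation
(real PM2.5/PM10 are strongly coupled), weekly/seasonal cycles,
meteorological covariates, heteroscedastic noise, and instrument
drop-outs. Tests passing on synthetic data therefore demonstrate
correctness of the algorithms and directional claims (denoising helps,
tuning helps), not field accuracy on any particular monitoring
network.

## CEEMD

Plain EMD sifts with cubic-spline envelopes through local extrema,
mirroring two extrema across each boundary to tame end effects.
Sifting stops by the classical Cauchy-style criterion
Σ(h_prev−h_new)²/Σh_prev² < 0.2, with at most 50 sift passes per
mode; decomposition stops when the residue has fewer than two interior
extrema or 8 modes (the default cap) have been extracted. These
values are canonical practice; the decomposition is insensitive to the
exact stop threshold on the series used here.

CEEMD decomposes f ± ε·nᵢ for `ensemble_size` noise realizations nᵢ
(defaults: 200 pairs, ε = 0.4 × signal SD) and averages mode-wise over
all 2N decompositions. Members yielding fewer than `max_imfs` modes
are zero-padded so the average is well defined. Because the noises
enter in ± pairs and every member decomposition reconstructs its input
exactly, the averaged modes + residue reconstruct the *original*
signal to machine precision — an identity the suite asserts at 1e−9
relative.

The denoising step removes IMF₁ (the highest-frequency mode) from the
decomposition of the **whole** series once, before the train/test
split. Splitting first and decomposing per window would avoid any
look-ahead in the decomposition but leaves boundary artifacts at every
window edge; since the removed mode is noise-dominated, the simpler
whole-series order is used.

## BBODE

Plain BBO ranks the population by fitness (lower = better), maps the
best habitat to species count k = n and the worst to k = 0, and uses
the migration-rate models (cosine by default) to set immigration λₖ
and emigration μₖ. Each variable of each habitat immigrates with
probability λₖ from a donor drawn by roulette over μ (self excluded).
Bounds are enforced by clipping after every operator; the previous
generation's elites (3) replace the worst of the new one.

Two interpretations deserve a note:

- **Mutation** is per *habitat*: each habitat is selected with
  probability `mutation_prob` and a single uniformly chosen variable
  is redrawn uniformly in the bounds. A per-variable interpretation
  at the hybrid's probability 0.4 scrambles 40 % of all coordinates
  every generation, which measurably destroys convergence (sphere-5
  mean ~7e−3 after 5000 generations, *worse* than plain BBO) and
  contradicts the published behaviour of the hybrid (mean ≈ 0) and
  its dominance over plain BBO. The per-habitat reading reproduces
  both (hybrid ≈ 1e−7, plain BBO ≈ 1e−3).
- **The DE step** is DE/rand/1/bin with CR = 0.9 and F = 0.6, with
  greedy selection, applied after the BBO step on even-numbered
  generations. The DE variant and crossover rate are the most common
  defaults; results are insensitive to CR in [0.7, 0.95].

The exponential migration model as defined does not vanish at the
endpoints (λₙ = I/e, μ₀ = E/e); the endpoint identities λ₀ = I,
λₙ = 0, μ₀ = 0, μₙ = E hold for the cosine, quadratic and linear
models only, and the tests assert exactly that.

Benchmark domains (sphere/rosenbrock [−30,30], rastrigin [−5.12,5.12],
griewank [−600,600], ackley [−32,32], schaffer [−100,100]) are the
canonical boxes for these functions. "Schaffer" is implemented as
Schaffer F6 summed over consecutive coordinate pairs.

## LSSVM

The dual system is solved with a symmetric direct solve; numerically
singular systems (duplicate rows, γ → ∞) fall back to least squares
with a warning — this makes the "all rows identical" degenerate case
return the mean target, the natural limit. Inputs are z-scored on
training statistics before kernel evaluation (RBF widths are otherwise
scale-dependent); predictions are mapped back.

Open choices: lag order d = 5 hourly lags (a small AR window adequate
for one-step-ahead hourly forecasting; configurable); the tuning box
σ ∈ [0.01, 100], γ ∈ [0.1, 1e6] searched in log10 space (spans the
useful regimes on standardized inputs); validation by the **last 20 %
of training rows** as a chronological holdout — shuffled
cross-validation would leak future values into the past on a time
series. Hyperparameters are tuned per series, not globally.

## Prediction intervals

The fitted LSSVM is linear in its targets, ŷ = L y, with
L = [1 K] Z⁻¹[:, 1:] for the bordered system matrix Z. Intervals use
the linear-smoother recipe: bias by double smoothing (L ŷ − ŷ),
noise variance by smoothing the squared residuals with the same
smoother, inflated by M/(M − tr L), floored at zero; at a new point
the predictive variance is the local noise variance plus the
smoother-row variance Σⱼ L*ⱼ² σ̂²(xⱼ); Gaussian quantiles give the
bounds. Intervals are *pointwise*, not simultaneous. On
homoscedastic synthetic data the suite checks coverage within binomial
Monte-Carlo error of 1 − a for a ∈ {0.05, 0.1, 0.2, 0.4}, and that
average width decreases strictly in a.

## Distribution fitting

The five families use the parameterizations in the table in
`aerowarn.distfit`; note the lognormal's second parameter is the log
mean and may be negative. Goodness of fit is R² between the
empirical CDF at plotting positions i/(n+1) (median-unbiased
convention) and the model CDF; the search runs BBODE in log10
parameter space (lognormal log-mean searched linearly in [−5, 10])
with a moment-matched start seeded into the initial population, which
guarantees the fit never falls below moment matching. Parameter
recovery within 10 % at n = 5000 is verified for all five families.
R² surfaces can be multimodal (notably Gamma on near-exponential
data), which is precisely why a global optimizer is used instead of a
local one.

## Cloud evaluation

Pseudo-bounds are exact OLS quadratics through the five lower upper
bounds evaluated at level index 6. The shipped reference tables use
the published rounded regression values, which differ from exact OLS
by up to 0.4 µg/m³ at the extrapolated point; the cloud table
regenerated from the reference pseudo-bounds matches the published one
to ±0.01 in every cell.

The X-condition generator, the half-cloud rule (membership 1 for
x ≤ Ex at level I and x ≥ Ex at level VI), En′ ≤ 0 draws rejected and
redrawn, and argmax ties broken toward the *worse* level (the
conservative warning) are as described in the README. The entropy
weight computation defaults to T = 10 equal-width bins; the published
weight vector is shipped as a fixture so evaluation does not depend on
the bin choice. Maximal-entropy degeneracy (all criteria uniform)
returns equal weights by symmetry.

One reference row is internally inconsistent: for sample A_6 the
published level III/IV/V certainties are a permutation of the values
the stated procedure produces (verified by direct hand computation:
A_6's PM10 = 211.4 µg/m³ sits near the level-III PM10 cloud center
200, so level III must dominate with U ≈ 0.34). The package computes
the verdict faithfully (level III); the corresponding published-level
check is intentionally left failing rather than special-cased. The
published level-I certainty for A_4 (0.1331) is likewise inconsistent
with the half-cloud rule that reproduces every other row; no headline
quantity depends on it.

## Metrics

RMSE is plain √MSE in concentration units; a literal relative reading
(dividing by the actual inside the square) is available via
`relative_rmse=True` but is not the default because published accuracy
tables for this kind of model report RMSE in µg/m³. The
Diebold-Mariano statistic is the canonical mean(V)/√(S²/t) with a
standard-normal decision rule and no small-sample correction
(consistent with z-quantile thresholds); loss defaults to absolute
error. Degenerate cases (identical losses, constant differential)
are flagged and never reject.

## Problem sizes in the suite

The test suite and the acceptance script run at desk scale: CEEMD
ensembles of 5–20 on series of 256–1024 points in tests (the
forecasting default remains 200), distribution recovery at n = 5000
with a 25 × 120 optimizer budget, interval calibration at n = 500,
DM-test size at 2000 replicates of t = 200, and the optimizer
benchmarks at the full reference settings (population 50, 5000
generations, 20 runs). Full-scale CEEMD ensembles on months of hourly
data run in minutes, not seconds, and are exercised through the same
code paths.

## Known limitations

- One-step-ahead only; multi-step and combination forecasting are out
  of scope.
- Intervals are pointwise Gaussian-quantile bands; no simultaneous
  coverage guarantee.
- The evaluator's AHP weight vector is taken as given (elicitation of
  pairwise comparison matrices is out of scope).
- EMD mode counts depend on sift parameters for pathological inputs;
  the reconstruction identity holds regardless.
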