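# Methods

## The model

`resicast` produces one-step-ahead forecasts of a univariate series
x₁…x_t by recursive residual correction. A base forecaster M₀ is fitted
to the series; its in-sample error series e₀ = x − M₀(x) is examined
for remaining temporal structure. While structure remains, a further
forecaster M_{i+1} is fitted to the current error series e_i, its own
residual e_{i+1} = e_i − M_{i+1}(e_i) is formed, and the loop repeats.
The final forecast is the sum of the stage predictions,

    x̂_{t+1} = M₀(x) + M₁(e₀) + M₂(e₁) + … + M_n(e_{n−1}),

so each stage contributes an additive correction to the one below it.
The premise is that a single forecaster is usually misspecified for a
real series — daily particulate-matter (PM2.5/PM10) concentrations mix
autocorrelated linear structure, nonlinear patterns and noise — and
that the part it misses is visible in, and partially recoverable from,
its residuals.

### The white-noise gate

Structure is detected with the sample autocorrelation function
ρ_k = γ_k/γ₀ (biased estimator, divisor N) of the training-segment
residual, k = 1…max_lag with max_lag = min(20, ⌊N/4⌋) by default. The
residual counts as white noise when the fraction of lags with
|ρ_k| > 2/√N does not exceed `acf.tolerance` (default 0: every lag must
lie inside the band). Note that with 20 lags the zero-tolerance rule
has a ≈ 64% false-alarm probability on genuinely white input
(1 − 0.954²⁰); a tolerance of 0.05, which forgives the single expected
false exceedance, is the statistically calibrated setting and is one
config key away. A ±2s band (twice the sample standard deviation of
the data) is also available as `acf.bound: two_s` for fidelity with a
looser informal statement of the rule, but it is scale-dependent and
essentially never rejects; the ±2/√N band is the defensible default.

### Stop rules

Corrections stop when (i) the training residual passes the white-noise
gate, (ii) the combined validation MAPE rises by ≥ 5% (relative,
stage over stage) for `patience` consecutive additions — those stages
are then excluded from the selected depth — or (iii) `max_corrections`
is reached. `patience` defaults to 1; setting it to 2 reproduces the
two-consecutive-increases variant of the rule. The stop metric is
computed on the validation segment only; the test segment is never
consulted during fitting. A final-depth ambiguity (keep the last stage
the stop rule allowed, or the depth with the best validation fitness)
is exposed as `correction.selection: stop_rule | best_val_fitness`;
only the latter guarantees the selected depth never scores below the
uncorrected model on validation fitness.

## Forecasters

### The MLP

Every stage is a single-hidden-layer perceptron on a lag window:
logistic-sigmoid hidden units, linear output (the series is min-max
scaled to [0, 1]; a linear output avoids saturation at the range
edges; a logistic output is available as a config option). Four
full-batch trainers are implemented against a shared exact Jacobian:
Levenberg–Marquardt (damped Gauss–Newton; damping ×0.3 on accepted
steps, ×10 on rejections), scaled conjugate gradient (Møller's
parameterization, σ₀ = 5·10⁻⁵, initial λ = 5·10⁻⁷), resilient
backpropagation (η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.1, Δ ∈ [10⁻⁶, 50]) and
one-step secant (Battiti's two-term direction with a backtracking line
search). Training stops at 1000 iterations (default), on a
generalization loss above 5% — GL(t) = 100·(E_val(t)/E_val_opt − 1),
with the best-validation weight snapshot restored — or when the
training error improves by less than 10⁻⁶ over a five-iteration
window. All weight initialization is seeded (uniform [−0.5, 0.5]
scaled by 1/√fan-in).

### Extrapolation guard

A fitted stage winsorizes its inputs at the per-lag training range and
clamps its output to the training-target range. This is a numerical
safeguard, not part of the statistical model: a sigmoid network driven
slightly outside the input hull it was fitted on can produce outputs an
order of magnitude beyond any residual ever observed, and validation
monitoring cannot catch it because the validation segment does not
probe the cliff. A residual model has no business predicting outside
the residual range it was trained against; within the hull the guard
is inactive.

### The hybrid system (HS)

The base forecaster of the reference protocol is a GA-searched MLP: a
small genetic algorithm evolves chromosomes (lag count ≤ 10, hidden
units ≤ 20, trainer ∈ {LM, SCG, RPROP, OSS}) guided by the validation
fitness

    Fitness = POCID / (1 + MSE + MAPE + U + ARV),

with POCID and MAPE on the percent scale, so fitness grows toward 100
as every error measure shrinks. GA settings: population 10, mutation
probability 0.10 (per-gene resampling), uniform crossover at rate 0.9,
tournament selection of size 2, elitism 1, at most 1000 generations,
early exit on fitness progress < 10⁻⁴ over a patience window or when
the best validation MAPE reaches 1%. Up to 10 independent restarts
(`max_outer_iterations`) share an evaluation cache and the best-ever
individual is kept. Each chromosome's training seed is derived from
the master seed and the gene values, so results are independent of
evaluation order. After the search, a phase adjustment
ŷ'(t) = a·ŷ(t+φ) + b (φ ∈ {0, 1}, least squares on the validation
segment) realigns a forecaster that lags behind the series; φ = 1 is
offered only when every input lag exceeds 1, which keeps the shifted
prediction causal, and the adjustment is kept only if it improves
validation fitness.

### Correction stages

Two correction methods are provided. `ann`: input lags 1..K where K is
the largest lag whose residual autocorrelation exceeds the band
(capped at 10; the sparse exceeding-lags-only variant is
`lag_mode: exceeding`, which proved noisier — borderline lags enter,
structural lags drop out), hidden units swept over [1, 20] by
validation MSE, trainer fixed to Levenberg–Marquardt. `hs`: the full
hybrid system fitted to the residual series.

## Metrics

MSE, MAPE (percent; terms with |target| < 10⁻⁸ are excluded and
counted, since min-max scaling forces at least one exact zero), Theil's
U, ARV, POCID (percent of steps whose predicted and actual direction
of change share a strict sign; the sum runs over the N−1 defined
transitions) and IA. U, ARV and IA follow the printed table forms used
in the reference protocol — U divides by summed squared successive
differences of the *forecast*, ARV and IA measure spread of the
forecast around the target mean — with the classical variants
(`u_denominator: targets`, `variant: classical`) available. Metrics
are computed on the normalized [0, 1] scale by default
(`metrics.scale: original` recomputes on concentration units). Ratio
reports divide each corrected metric by its uncorrected counterpart;
both stage-over-stage (Cₙ/Cₙ₋₁) and best-over-base (Cₙ/C₀) pairings
are emitted.

## Experimental protocol

`run_experiment` min-max normalizes (fitted on the full series by
default, matching the reference protocol; `normalization.fit_on: train`
for leak-free operation), splits chronologically 80/10/10 (floor-based
boundaries, remainder to the test segment; 50/20/30 and 50/30/20 are
preset sensitivity splits), runs ten seeded repetitions of the chain
fit, and reports the repetition with the best validation fitness at
its selected depth. Per-stage metric rows, ratio rows and ACF traces
are rendered to CSV/JSON with the resolved config and master seed
alongside.

## The synthetic generators

No real concentration data ships with the package; seeded generators
emulate the structure the method assumes.

- `gen_white_noise`: i.i.d. Gaussian — the stopping condition.
- `gen_ar`: stationary AR(p), burn-in of 10·p discarded.
- `gen_composite`: linear AR(2) part (coefficients 0.6, −0.2, unit
  innovations) + a nonlinear component whose standard deviation is
  half that of the linear part + white noise at a signal-to-noise
  variance ratio of 5, with the three components returned separately
  and summing exactly. The default nonlinear form is a delay-2
  threshold-AR term (steeper response to the linear part two steps
  back when it is positive). This choice is deliberate: the component
  must be *recoverable from lag windows of the residual* for the
  correction chain to have signal to find. A deterministic seasonal
  sinusoid in noise is recoverable only in proportion to ρ_k² per lag
  (a few percent of residual variance at these amplitude/noise
  settings — we verified with a least-squares oracle on residual lags
  that no lag-based corrector can improve materially on it), whereas
  the delay-2 threshold term leaves strong stochastic lag-2 structure
  that a one-lag base cannot touch and a lagged correction model can.
  A sinusoid-modulated AR (time-varying lag-1 coefficient, default
  period 7 — a weekly cycle, the natural periodicity of daily
  pollution data) and a quadratic lag term are the other forms.
- `gen_pm_like`: exp(log 15 + annual sinusoid + AR(1) φ=0.7,
  σ=0.4) — strictly positive, right-skewed, autocorrelated daily
  concentrations with a median near 15 µg/m³.

What the generators do *not* emulate: missing values and irregular
sampling, meteorological covariates, regime changes and extreme
episodes (dust storms), measurement error, and the heavy upper tail of
real urban PM records beyond log-normality. Passing tests on synthetic
data therefore demonstrate the machinery (gating, training, additivity,
selection, reproducibility) and the method's behavior under its own
assumptions — not field performance on any particular monitoring
station.

## Numerical choices and degenerate inputs

- Min-max scaling of a constant series raises a degenerate-scale error;
  ACF of a constant series raises a zero-variance error; in-chain, a
  constant or too-short (< 8 points) training residual is treated as
  unstructured and stops the loop.
- Splits must leave every segment non-empty; window construction
  requires the series to outlast its largest lag.
- Non-finite training loss reverts to the best snapshot and flags the
  model as diverged.
- Lag-window columns are ordered oldest to newest; residual arrays
  carry NaN heads where no complete window exists, and every consumer
  masks on finiteness.
- MAPE's zero-target guard (ε = 10⁻⁸) and its exclusion count are
  reported in every metrics row.
- Fixed tie-break in the hidden sweep: the first candidate at the
  minimal validation MSE wins (smallest hidden count first).

## Problem sizes

The test suite and the worked examples run the generators at n =
400–600 with training capped at 100–150 iterations, GA populations of
6–10 over a handful of generations, and correction sweeps over 2–4
hidden sizes; these sizes are where the statistical effects under test
are already stable, and they keep the full suite under a minute. The
package defaults (1000 iterations, 1000 generations, sweep 1..20, 10
restarts) match the reference protocol and are what `resicast correct`
uses unless a config says otherwise.

## Known limitations

- One step ahead only; no multi-step recursion or direct multi-horizon
  models.
- Univariate only; no exogenous inputs.
- The MAPE-driven stop rule is unstable when validation targets sit
  near zero (min-max scaling guarantees one exact zero somewhere; if it
  lands in the validation segment the guard excludes it, but
  near-zero targets still inflate the metric).
- With 60-point validation and test segments, validation preference
  and test performance disagree in a nontrivial fraction of runs; a
  correction stage that validation genuinely favors can hurt the test
  segment. Larger validation segments (the 50/30/20 preset) trade
  training data for steadier selection.
- The GA is a small single-objective search; it does not explore
  activation functions, lag subsets, or architectures beyond one
  hidden layer.
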