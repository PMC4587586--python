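# resicast

Recursive residual-correction forecasting for univariate time series,
built for the setting of daily air-pollutant concentrations (PM2.5 and
PM10), where a single forecaster is almost always misspecified: the
series mix autocorrelated linear structure, nonlinear patterns and
noise, and whatever the model misses survives in its residuals.

`resicast` fits a base forecaster M₀, checks its error series
e₀ = x − M₀(x) for remaining temporal structure with the
autocorrelation function, and — while structure remains — fits further
forecasters to the successive error series, adding their outputs to the
final one-step-ahead prediction:

    x̂_{t+1} = M₀(x) + M₁(e₀) + M₂(e₁) + … + M_n(e_{n−1})

The loop stops when the residual behaves like white noise (all
autocorrelations inside the ±2/√N band), when an added correction
inflates the validation MAPE by ≥ 5%, or at a depth cap. The base
forecaster is either a fixed MLP or a hybrid system (HS): a genetic
algorithm searching the MLP's lag count, hidden size and trainer
(Levenberg–Marquardt, scaled conjugate gradient, RPROP, one-step
secant), scored by the validation fitness

    Fitness = POCID / (1 + MSE + MAPE + U + ARV)

followed by an optional phase adjustment. Corrections are modeled
either by an ACF-configured MLP or by the HS itself. Forecasts are
evaluated with six standard measures — MSE, MAPE, Theil's U, ARV,
POCID, index of agreement — plus the fitness score, and corrected
models are compared to uncorrected ones through per-metric ratios.

No proprietary data is required: seeded generators produce series with
the assumed structure (stationary AR, composite linear + nonlinear +
noise, and positive right-skewed PM-like daily series), so the whole
pipeline is testable offline. See `docs/methods.md` for the model
details, parameter meanings and limitations.

## Worked example

Fit the correction chain to a synthetic composite series (AR(2) plus a
delay-2 threshold nonlinearity plus noise) with a deliberately weak
one-lag base model, ten seeded repetitions, best repetition selected by
validation fitness:

```python
import resicast as rc

cfg = rc.config_from_dict({
    "base": {"kind": "mlp", "mlp": {"n_lags": 1, "n_hidden": 2, "trainer": "lm"}},
    "train": {"max_iterations": 150},
    "correction": {"method": "ann", "hidden_sweep": [1, 2, 4, 8],
                   "stop": {"max_corrections": 3}, "selection": "best_val_fitness"},
    "experiment": {"repetitions": 10},
    "seed": 2024,
})
series = rc.gen_composite(600, seed=2).series
report = rc.run_experiment(series, cfg)
```

which prints (via the report's stage rows):

```
stop: white_noise  selected depth: 2  best repetition: 4
MLP            MSE 1.72E-02  POCID 42.37  U 4.6519  MAPE 28.14  ARV 3.4594  IA 0.621  Fitness 1.14
MLP+C1         MSE 1.65E-02  POCID 42.37  U 4.4768  MAPE 27.34  ARV 2.6324  IA 0.657  Fitness 1.19
MLP+C1+...+C2  MSE 1.60E-02  POCID 55.93  U 2.5940  MAPE 27.15  ARV 1.7118  IA 0.712  Fitness 1.72
ratio C1-C0   MSE 0.961  MAPE 0.971  Fitness 1.051
ratio C2-C1   MSE 0.968  MAPE 0.993  Fitness 1.442
ratio C2-C0   MSE 0.930  MAPE 0.965  Fitness 1.515
```

Two corrections were accepted before the residual passed the
white-noise gate. Each row evaluates the cumulative forecast on the
held-out test segment (normalized scale): test MSE falls 7% from the
uncorrected base to the selected depth, the direction-of-change score
(POCID) rises from 42 to 56%, and the fitness ratio of 1.515 in the
final row summarizes the corrected-over-uncorrected improvement.
Ratios below 1 for error metrics and above 1 for fitness mean the
correction helped.

The same run from a shell:

```bash
resicast simulate --kind composite --n 600 --seed 2 --out series.csv
resicast correct --input series.csv --config run.yaml --out report/
```

writes `metrics.csv` and `ratios.csv` (the rows above), per-stage ACF
traces, a JSON twin of the report, and a run log with the resolved
configuration and master seed. `resicast acf` and `resicast evaluate`
expose the white-noise diagnostic and the metric suite on their own.

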