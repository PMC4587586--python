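"""Recursive residual correction: ACF white-noise gate, residual
forecasters, and the additive chain forecast.

The idea: a base forecaster M0 rarely captures everything.  Its error
series e0 = x - M0(x) is tested for white-noise behavior via the
autocorrelation function (ACF).  While structure remains, a further
forecaster M_{i+1} is trained on the current error series e_i, its own
residual e_{i+1} = e_i - M_{i+1}(e_i) is formed, and the loop repeats.
The final one-step-ahead forecast is the sum of the stage predictions:

    x_hat(t+1) = M0(x) + M1(e0) + M2(e1) + ... + Mn(e_{n-1})

The loop stops when (i) the training residual behaves like white noise,
(ii) the combined validation MAPE rises by at least a configured
fraction for ``patience`` consecutive added corrections (those stages
are then excluded from the selected depth), or (iii) a cap on the number
of corrections is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .forecast import FittedForecaster
from .metrics import MetricsReport, evaluate_all
from .series import InsufficientDataError, SplitSpec, TimeSeries

__all__ = [
    "ACFResult",
    "StopPolicy",
    "StageRecord",
    "CorrectionChain",
    "acf",
    "white_noise_test",
    "fit_correction_chain",
    "chain_forecast",
]

# factory(values, train_end, val_end, seed) -> FittedForecaster trained on
# window rows whose target index is < train_end, validated on rows with
# target index in [train_end, val_end)
ForecasterFactory = Callable[[np.ndarray, int, int, int], FittedForecaster]


# ----------------------------------------------------------------------
# ACF and the white-noise gate
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class ACFResult:
    """Sample autocorrelations rho_k for k = 1..max_lag with per-lag
    two-sided bounds and the white-noise verdict."""

    rho: np.ndarray
    bound: np.ndarray
    n: int
    is_white_noise: bool
    n_exceeding: int
    tolerance_fraction: float = 0.0

    @property
    def lags(self) -> np.ndarray:
        return np.arange(1, self.rho.size + 1)

    @property
    def exceeding_lags(self) -> np.ndarray:
        return self.lags[np.abs(self.rho) > self.bound]

    def as_dict(self) -> dict:
        return {
            "lags": self.lags.tolist(),
            "rho": self.rho.tolist(),
            "bound": self.bound.tolist(),
            "n": self.n,
            "is_white_noise": self.is_white_noise,
            "n_exceeding": self.n_exceeding,
        }


def acf(
    series: TimeSeries | np.ndarray,
    max_lag: int | None = None,
    bound: str = "two_over_sqrt_n",
    tolerance_fraction: float = 0.0,
) -> ACFResult:
    """Sample ACF with the biased (divisor N) autocovariance estimator.

    rho_k = sum_{t} (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2.

    ``bound`` selects the two-sided no-correlation band: the standard
    large-sample band ``2/sqrt(N)`` (default) or ``two_s``, twice the
    sample standard deviation of the data (a much wider, scale-dependent
    band kept for fidelity with a literal reading of the rule).
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    n = x.size
    if max_lag is None:
        max_lag = min(20, n // 4)
    if max_lag < 1 or n <= max_lag:
        raise ValueError(f"need series length > max_lag >= 1 (n={n}, max_lag={max_lag})")
    xc = x - x.mean()
    gamma0 = float(xc @ xc)
    if gamma0 == 0.0:
        raise ValueError("constant series has zero variance; ACF undefined")
    rho = np.array([float(xc[: n - k] @ xc[k:]) / gamma0 for k in range(1, max_lag + 1)])
    if bound == "two_over_sqrt_n":
        b = np.full(max_lag, 2.0 / math.sqrt(n))
    elif bound == "two_s":
        b = np.full(max_lag, 2.0 * float(np.std(x)))
    else:
        raise ValueError("bound must be 'two_over_sqrt_n' or 'two_s'")
    n_exceeding = int(np.sum(np.abs(rho) > b))
    is_white = (n_exceeding / max_lag) <= tolerance_fraction
    return ACFResult(rho, b, n, is_white, n_exceeding, tolerance_fraction)


def white_noise_test(acf_result: ACFResult, tolerance_fraction: float = 0.0) -> bool:
    """True iff the fraction of lags outside the bounds is at most
    ``tolerance_fraction`` (0 = the literal all-lags-inside rule)."""
    return (acf_result.n_exceeding / acf_result.rho.size) <= tolerance_fraction


# ----------------------------------------------------------------------
# the correction chain
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class StopPolicy:
    """When to stop adding corrections.

    ``mape_increase_threshold`` is the relative validation-MAPE increase
    (stage over stage) that counts as a degradation; ``patience``
    consecutive degradations trigger the stop and exclude the offending
    stages.  ``max_corrections`` caps the number of correction models.
    """

    mape_increase_threshold: float = 0.05
    patience: int = 1
    max_corrections: int = 5

    def __post_init__(self) -> None:
        if self.mape_increase_threshold <= 0:
            raise ValueError("mape_increase_threshold must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_corrections < 0:
            raise ValueError("max_corrections must be >= 0")


@dataclass
class StageRecord:
    """Diagnostics for one chain stage (cumulative up to this depth)."""

    depth: int
    label: str
    val_report: MetricsReport
    test_report: MetricsReport
    acf_result: ACFResult | None  # ACF of this stage's training residual
    val_mape: float
    mape_increased: bool = False


@dataclass
class CorrectionChain:
    """Ordered models M0..Mn with their residual series and diagnostics.

    ``stage_preds[i]`` and ``residuals[i]`` are full-length arrays with
    NaN heads where no complete lag window exists; ``residuals[i]`` is
    the input of stage i minus stage i's predictions at every aligned
    index.  ``selected_depth`` is the deepest stage retained for
    forecasting after the stop rule.
    """

    forecasters: list[FittedForecaster]
    stage_preds: list[np.ndarray]
    residuals: list[np.ndarray]
    records: list[StageRecord]
    stop_reason: str
    selected_depth: int
    train_end: int
    val_end: int
    series_values: np.ndarray

    @property
    def depth(self) -> int:
        return len(self.forecasters) - 1

    def combined_prediction(self, depth: int | None = None) -> np.ndarray:
        """Elementwise sum of stage predictions up to ``depth`` (full
        length, NaN where the deepest stage has no window yet)."""
        d = self.selected_depth if depth is None else depth
        out = self.stage_preds[0].copy()
        for p in self.stage_preds[1 : d + 1]:
            out = out + p
        return out

    def to_dict(self) -> dict:
        return {
            "forecasters": [f.to_dict() for f in self.forecasters],
            "stop_reason": self.stop_reason,
            "selected_depth": self.selected_depth,
            "train_end": self.train_end,
            "val_end": self.val_end,
            "series_values": self.series_values.tolist(),
        }


def _segment_metrics(
    targets: np.ndarray, preds: np.ndarray, lo: int, hi: int, **metric_kw
) -> MetricsReport:
    sel = slice(lo, hi)
    t, p = targets[sel], preds[sel]
    ok = np.isfinite(p)
    return evaluate_all(t[ok], p[ok], **metric_kw)


def fit_correction_chain(
    series: TimeSeries,
    base_factory: ForecasterFactory,
    correction_factory: ForecasterFactory,
    split: SplitSpec,
    policy: StopPolicy,
    seed: int = 0,
    *,
    acf_bound: str = "two_over_sqrt_n",
    acf_tolerance: float = 0.0,
    acf_max_lag: int | None = None,
    metric_kw: dict | None = None,
    selection: str = "stop_rule",
) -> CorrectionChain:
    """Train the base model and recursively correct its residuals.

    The series is split chronologically; all models are fitted on the
    training segment (with validation-segment monitoring) and the stop
    policy is driven by the combined validation MAPE.  The test segment
    is never touched during fitting -- its metrics are recorded for
    reporting only.

    ``selection`` picks the final depth: ``"stop_rule"`` keeps the last
    stage not excluded by the stop policy (the chain as grown);
    ``"best_val_fitness"`` picks the depth with the highest validation
    fitness, which guarantees the selected depth is never worse than
    the uncorrected model on that score.
    """
    if selection not in ("stop_rule", "best_val_fitness"):
        raise ValueError("selection must be 'stop_rule' or 'best_val_fitness'")
    metric_kw = metric_kw or {}
    x = series.values
    n = x.size
    i1 = int(np.floor(n * split.train_frac))
    i2 = int(np.floor(n * (split.train_frac + split.val_frac)))

    ss = np.random.SeedSequence(seed)
    stage_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(policy.max_corrections + 1)]

    def stage_predictions(f: FittedForecaster, inp: np.ndarray, offset: int) -> np.ndarray:
        full = np.full(n, np.nan)
        full[offset:] = f.predict_series(inp[offset:])
        return full

    def train_residual_acf(resid: np.ndarray) -> ACFResult | None:
        r = resid[:i1]
        r = r[np.isfinite(r)]
        if r.size < 8 or float(np.var(r)) == 0.0:
            return None  # too short / degenerate: treat as unstructured
        max_lag = acf_max_lag or min(20, r.size // 4)
        if max_lag < 1:
            return None
        return acf(r, max_lag, acf_bound, acf_tolerance)

    forecasters: list[FittedForecaster] = []
    stage_preds: list[np.ndarray] = []
    residuals: list[np.ndarray] = []
    records: list[StageRecord] = []

    # ---- stage 0: the base forecaster on the series itself ------------
    f0 = base_factory(x, i1, i2, stage_seeds[0])
    forecasters.append(f0)
    stage_preds.append(stage_predictions(f0, x, 0))
    residuals.append(x - stage_preds[0])

    def record_stage(depth: int, increased: bool) -> StageRecord:
        combined = np.sum(stage_preds[: depth + 1], axis=0)
        val_rep = _segment_metrics(x, combined, i1, i2, **metric_kw)
        test_rep = _segment_metrics(x, combined, i2, n, **metric_kw)
        label = "M0" if depth == 0 else f"M0+C{depth}"
        rec = StageRecord(
            depth=depth,
            label=label,
            val_report=val_rep,
            test_report=test_rep,
            acf_result=train_residual_acf(residuals[depth]),
            val_mape=val_rep.mape,
            mape_increased=increased,
        )
        records.append(rec)
        return rec

    rec = record_stage(0, increased=False)
    prev_mape = rec.val_mape
    increase_run = 0
    stop_reason = "max_corrections"
    depth = 0

    while True:
        if depth >= policy.max_corrections:
            stop_reason = "max_corrections"
            break
        acf_res = records[depth].acf_result
        if acf_res is None or white_noise_test(acf_res, acf_tolerance):
            stop_reason = "white_noise"
            break

        resid = residuals[depth]
        offset = int(np.argmax(np.isfinite(resid)))  # first defined index
        try:
            f_next = correction_factory(
                resid[offset:], i1 - offset, i2 - offset, stage_seeds[depth + 1]
            )
        except (ValueError, InsufficientDataError, np.linalg.LinAlgError):
            stop_reason = "stage_failure"
            break

        # re-wrap: the factory worked on the trimmed residual, so its
        # predictions must be re-aligned onto the full index range
        full_pred = np.full(n, np.nan)
        full_pred[offset:] = f_next.predict_series(resid[offset:])
        forecasters.append(f_next)
        stage_preds.append(full_pred)
        residuals.append(resid - full_pred)
        depth += 1

        rec = record_stage(depth, increased=False)
        if (
            np.isfinite(prev_mape)
            and np.isfinite(rec.val_mape)
            and prev_mape > 0
            and (rec.val_mape - prev_mape) / prev_mape >= policy.mape_increase_threshold
        ):
            increase_run += 1
            rec.mape_increased = True
        else:
            increase_run = 0
        prev_mape = rec.val_mape
        if increase_run >= policy.patience:
            stop_reason = "mape_increase"
            break

    if stop_reason == "mape_increase":
        selected = depth - increase_run  # drop the degrading stages
    else:
        selected = depth
    if selection == "best_val_fitness":
        fits = [
            r.val_report.fitness if np.isfinite(r.val_report.fitness) else -np.inf
            for r in records
        ]
        selected = int(np.argmax(fits))

    return CorrectionChain(
        forecasters=forecasters,
        stage_preds=stage_preds,
        residuals=residuals,
        records=records,
        stop_reason=stop_reason,
        selected_depth=selected,
        train_end=i1,
        val_end=i2,
        series_values=x.copy(),
    )


def chain_forecast(chain: CorrectionChain, history: TimeSeries | np.ndarray) -> float:
    """One-step-ahead forecast for the index just past ``history``.

    Computes each stage's residual history causally (from past actuals
    and past stage outputs only) and sums the stage predictions up to
    the selected depth.
    """
    cur = history.values if isinstance(history, TimeSeries) else np.asarray(history, float)
    total = 0.0
    for i, f in enumerate(chain.forecasters[: chain.selected_depth + 1]):
        total += f.predict_next(cur)
        if i < chain.selected_depth:
            preds = f.predict_series(cur)
            nxt = cur - preds
            nxt = nxt[np.isfinite(nxt)]
            if nxt.size == 0:
                raise InsufficientDataError("history too short for the chain's lag windows")
            cur = nxt
    return float(total)


# ----------------------------------------------------------------------
# correction factories
# ----------------------------------------------------------------------


def ann_correction_factory(
    hidden_sweep: Sequence[int] = tuple(range(1, 21)),
    max_acf_lags: int = 10,
    train_opts=None,
    acf_bound: str = "two_over_sqrt_n",
    lag_mode: str = "consecutive",
) -> ForecasterFactory:
    """Correction network in the ACF-guided configuration.

    The input window is chosen from the training-segment ACF of the
    residual: with ``lag_mode="consecutive"`` (default) the inputs are
    all lags 1..K where K is the largest lag whose autocorrelation
    exceeds the no-correlation bound (capped at ``max_acf_lags``); with
    ``lag_mode="exceeding"`` only the exceeding lags themselves are
    used.  Either way the choice falls back to lag 1 when no lag
    exceeds the bound.  The hidden layer size is swept over
    ``hidden_sweep`` picking the lowest validation MSE, and the trainer
    is Levenberg-Marquardt.
    """
    from .mlp import MLPConfig, TrainOptions, init_model, train as train_mlp
    from .hybrid import _split_windows

    opts = train_opts or TrainOptions()
    if lag_mode not in ("consecutive", "exceeding"):
        raise ValueError("lag_mode must be 'consecutive' or 'exceeding'")

    def factory(values: np.ndarray, train_end: int, val_end: int, seed: int) -> FittedForecaster:
        train_part = values[:train_end]
        max_lag = min(20, train_part.size // 4)
        if max_lag < 1:
            raise InsufficientDataError("training segment too short for ACF lag choice")
        res = acf(train_part, max_lag, acf_bound)
        exceeding = [int(k) for k in res.exceeding_lags]
        if lag_mode == "consecutive":
            k_max = min(max(exceeding), max_acf_lags) if exceeding else 1
            chosen = list(range(1, k_max + 1))
        else:
            chosen = exceeding[:max_acf_lags] or [1]
        lags = tuple(sorted(chosen, reverse=True))

        tr, va = _split_windows(values, train_end, val_end, chosen)
        best = None
        for j, h in enumerate(hidden_sweep):
            cfg = MLPConfig(n_inputs=len(lags), n_hidden=int(h), trainer="lm",
                            seed=(seed + 7919 * j) % (2**31 - 1))
            model = train_mlp(init_model(cfg), tr, va, opts)
            val_mse = float(np.mean((np.asarray(
                _forward_windows(model, va)) - va.targets) ** 2))
            if best is None or val_mse < best[0]:
                best = (val_mse, model)
        assert best is not None
        bounds = (float(tr.targets.min()), float(tr.targets.max()))
        ib = (tr.inputs.min(axis=0), tr.inputs.max(axis=0))
        return FittedForecaster(best[1], lags, output_bounds=bounds, input_bounds=ib)

    return factory


def _forward_windows(model, window_set):
    from .mlp import forward
    return forward(model, window_set.inputs)


def hybrid_correction_factory(params, train_opts=None) -> ForecasterFactory:
    """Correction stage fitted by the full hybrid system (GA + phase
    adjustment) on the residual series."""
    from .hybrid import GAParams, fit_hybrid

    assert isinstance(params, GAParams)

    def factory(values: np.ndarray, train_end: int, val_end: int, seed: int) -> FittedForecaster:
        from dataclasses import replace

        tr = TimeSeries(values[:train_end], "residual/train")
        va = TimeSeries(values[train_end:val_end], "residual/val")
        model = fit_hybrid(tr, va, replace(params, seed=seed), train_opts)
        return model.forecaster

    return factory


def hybrid_base_factory(params, train_opts=None) -> ForecasterFactory:
    """Base forecaster: the hybrid system fitted on the series itself."""
    from .hybrid import GAParams, fit_hybrid

    assert isinstance(params, GAParams)

    def factory(values: np.ndarray, train_end: int, val_end: int, seed: int) -> FittedForecaster:
        from dataclasses import replace

        tr = TimeSeries(values[:train_end], "series/train")
        va = TimeSeries(values[train_end:val_end], "series/val")
        model = fit_hybrid(tr, va, replace(params, seed=seed), train_opts)
        return model.forecaster

    return factory


def mlp_base_factory(n_lags: int, n_hidden: int, trainer: str = "lm", train_opts=None) -> ForecasterFactory:
    """Plain fixed-architecture MLP base forecaster (no GA search)."""
    from .mlp import MLPConfig, TrainOptions, init_model, train as train_mlp
    from .hybrid import _split_windows

    opts = train_opts or TrainOptions()

    def factory(values: np.ndarray, train_end: int, val_end: int, seed: int) -> FittedForecaster:
        tr, va = _split_windows(values, train_end, val_end, n_lags)
        cfg = MLPConfig(n_inputs=n_lags, n_hidden=n_hidden, trainer=trainer, seed=seed)
        model = train_mlp(init_model(cfg), tr, va, opts)
        bounds = (float(tr.targets.min()), float(tr.targets.max()))
        ib = (tr.inputs.min(axis=0), tr.inputs.max(axis=0))
        return FittedForecaster(
            model, tuple(range(n_lags, 0, -1)), output_bounds=bounds, input_bounds=ib
        )

    return factory
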