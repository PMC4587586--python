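"""Hybrid GA + MLP forecaster ("hybrid system", HS).

A small genetic algorithm searches the MLP structure space -- number of
input lags, number of hidden units, and the training algorithm (one of
``lm``, ``scg``, ``rprop``, ``oss``) -- guided by the fitness score of
each candidate's one-step-ahead forecasts on the validation segment.
After the search an optional phase-adjustment stage fits an affine
realignment of the forecasts against the validation targets and keeps it
only if it improves validation fitness.

GA operators (not fixed by the method's definition, so configurable):
tournament selection of size 2, uniform crossover, per-gene resampling
mutation, elitism of one individual.  Each chromosome evaluation is
seeded deterministically from the master seed and the gene values, so
the search is reproducible and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forecast import FittedForecaster, PhaseAdjustment
from .metrics import MetricsReport, evaluate_all
from .mlp import TRAINERS, MLPConfig, TrainOptions, init_model, train
from .series import SupervisedWindowSet, TimeSeries, make_lag_matrix

__all__ = ["Chromosome", "GAParams", "HybridModel", "ga_search", "phase_adjust", "fit_hybrid"]


@dataclass(frozen=True)
class Chromosome:
    """GA genotype: lag count, hidden units, trainer index (0..3)."""

    n_lags: int
    n_hidden: int
    trainer_id: int

    def validate(self, max_lags: int, max_hidden: int) -> None:
        if not (1 <= self.n_lags <= max_lags):
            raise ValueError(f"n_lags must be in [1, {max_lags}]")
        if not (1 <= self.n_hidden <= max_hidden):
            raise ValueError(f"n_hidden must be in [1, {max_hidden}]")
        if not (0 <= self.trainer_id < len(TRAINERS)):
            raise ValueError("trainer_id must index one of the four trainers")

    @property
    def trainer(self) -> str:
        return TRAINERS[self.trainer_id]


@dataclass(frozen=True)
class GAParams:
    """Search-budget and operator settings for the hybrid system."""

    mutation_prob: float = 0.10
    pop_size: int = 10
    max_generations: int = 1000
    min_fitness_progress: float = 1e-4
    acceptable_fitness_error: float = 0.01  # fraction; early exit at val MAPE <= 1%
    max_lags: int = 10
    max_hidden: int = 20
    max_outer_iterations: int = 10
    seed: int = 0
    crossover_rate: float = 0.9
    tournament_size: int = 2
    elitism: int = 1
    progress_patience: int = 10  # generations without min_fitness_progress
    phase_adjustment: str = "affine_shift"  # or "none"
    allowed_trainers: tuple = TRAINERS

    def __post_init__(self) -> None:
        if not self.allowed_trainers or any(t not in TRAINERS for t in self.allowed_trainers):
            raise ValueError(f"allowed_trainers must be a non-empty subset of {TRAINERS}")
        for name in ("pop_size", "max_generations", "max_lags", "max_hidden",
                     "max_outer_iterations", "tournament_size", "progress_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("mutation_prob", "crossover_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_fitness_progress <= 0 or self.acceptable_fitness_error <= 0:
            raise ValueError("progress and error thresholds must be positive")
        if self.phase_adjustment not in ("affine_shift", "none"):
            raise ValueError("phase_adjustment must be 'affine_shift' or 'none'")


@dataclass
class HybridModel:
    """Best individual found by the search, with its trained network."""

    best_chromosome: Chromosome
    forecaster: FittedForecaster
    validation_report: MetricsReport
    search_log: list = field(default_factory=list)  # (generation, best, mean)
    phase_applied: bool = False


def _chromosome_seed(master_seed: int, c: Chromosome) -> int:
    # order-independent, deterministic per (seed, genes)
    return int(
        (master_seed * 1_000_003 + c.n_lags * 10_007 + c.n_hidden * 101 + c.trainer_id)
        % (2**31 - 1)
    )


def _split_windows(
    values: np.ndarray, train_end: int, val_end: int, lag_spec
) -> tuple[SupervisedWindowSet, SupervisedWindowSet]:
    """Windows over the contiguous train+val stretch, rows assigned to the
    segment that holds their *target* index (lag inputs may cross the
    boundary backwards, which is causal)."""
    windows = make_lag_matrix(values[:val_end], lag_spec)
    in_train = windows.target_indices < train_end
    if not np.any(in_train) or not np.any(~in_train):
        raise ValueError("segments too short for the requested lag window")
    tr = SupervisedWindowSet(
        windows.inputs[in_train], windows.targets[in_train], windows.lags,
        windows.target_indices[in_train],
    )
    va = SupervisedWindowSet(
        windows.inputs[~in_train], windows.targets[~in_train], windows.lags,
        windows.target_indices[~in_train],
    )
    return tr, va


def _evaluate_chromosome(
    c: Chromosome,
    values: np.ndarray,
    train_end: int,
    val_end: int,
    master_seed: int,
    train_opts: TrainOptions,
) -> tuple[FittedForecaster, MetricsReport]:
    tr, va = _split_windows(values, train_end, val_end, c.n_lags)
    cfg = MLPConfig(
        n_inputs=c.n_lags,
        n_hidden=c.n_hidden,
        trainer=c.trainer,
        seed=_chromosome_seed(master_seed, c),
    )
    model = train(init_model(cfg), tr, va, train_opts)
    bounds = (float(tr.targets.min()), float(tr.targets.max()))
    ib = (tr.inputs.min(axis=0), tr.inputs.max(axis=0))
    forecaster = FittedForecaster(
        model, tuple(range(c.n_lags, 0, -1)), output_bounds=bounds, input_bounds=ib
    )
    preds = forecaster.predict_series(values[:val_end])
    sel = slice(max(train_end, c.n_lags), val_end)
    report = evaluate_all(values[sel], preds[sel])
    return forecaster, report


def _trainer_ids(p: GAParams) -> list[int]:
    return [TRAINERS.index(t) for t in p.allowed_trainers]


def _random_chromosome(rng: np.random.Generator, p: GAParams) -> Chromosome:
    ids = _trainer_ids(p)
    return Chromosome(
        int(rng.integers(1, p.max_lags + 1)),
        int(rng.integers(1, p.max_hidden + 1)),
        ids[int(rng.integers(0, len(ids)))],
    )


def _mutate(c: Chromosome, rng: np.random.Generator, p: GAParams) -> Chromosome:
    genes = [c.n_lags, c.n_hidden, c.trainer_id]
    ids = _trainer_ids(p)
    if rng.random() < p.mutation_prob:
        genes[0] = int(rng.integers(1, p.max_lags + 1))
    if rng.random() < p.mutation_prob:
        genes[1] = int(rng.integers(1, p.max_hidden + 1))
    if rng.random() < p.mutation_prob:
        genes[2] = ids[int(rng.integers(0, len(ids)))]
    return Chromosome(*genes)


def _crossover(a: Chromosome, b: Chromosome, rng: np.random.Generator) -> Chromosome:
    ga, gb = (a.n_lags, a.n_hidden, a.trainer_id), (b.n_lags, b.n_hidden, b.trainer_id)
    picks = rng.random(3) < 0.5
    return Chromosome(*[x if take else y for x, y, take in zip(ga, gb, picks)])


def _tournament(pop, fits, rng: np.random.Generator, size: int) -> Chromosome:
    idx = rng.integers(0, len(pop), size=size)
    return pop[max(idx, key=lambda i: fits[i])]


def _ga_once(
    values: np.ndarray,
    train_end: int,
    val_end: int,
    params: GAParams,
    run_seed: int,
    train_opts: TrainOptions,
    cache: dict,
) -> HybridModel:
    rng = np.random.default_rng(run_seed)

    def score(c: Chromosome):
        key = (c.n_lags, c.n_hidden, c.trainer_id)
        if key not in cache:
            try:
                cache[key] = _evaluate_chromosome(
                    c, values, train_end, val_end, params.seed, train_opts
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                cache[key] = exc
        res = cache[key]
        if isinstance(res, Exception):
            return None
        return res

    pop = [_random_chromosome(rng, params) for _ in range(params.pop_size)]
    best: tuple[Chromosome, FittedForecaster, MetricsReport] | None = None
    log: list[tuple[int, float, float]] = []
    last_progress_best = -np.inf
    stalled = 0

    for gen in range(params.max_generations):
        scored = [(c, score(c)) for c in pop]
        fits = [
            (r[1].fitness if r is not None and np.isfinite(r[1].fitness) else -np.inf)
            for _, r in scored
        ]
        if all(f == -np.inf for f in fits):
            raise RuntimeError("every chromosome evaluation failed")
        gen_best = int(np.argmax(fits))
        if best is None or fits[gen_best] > best[2].fitness or not np.isfinite(best[2].fitness):
            c, r = scored[gen_best]
            if r is not None:
                best = (c, r[0], r[1])
        finite = [f for f in fits if f != -np.inf]
        log.append((gen, max(finite), float(np.mean(finite))))

        # stop rules: acceptable validation error, fitness-progress stall
        if best is not None and np.isfinite(best[2].mape) and (
            best[2].mape <= 100.0 * params.acceptable_fitness_error
        ):
            break
        if best is not None:
            if best[2].fitness - last_progress_best >= params.min_fitness_progress:
                last_progress_best = best[2].fitness
                stalled = 0
            else:
                stalled += 1
                if stalled >= params.progress_patience:
                    break
        if gen == params.max_generations - 1:
            break

        elite_idx = np.argsort(fits)[::-1][: params.elitism]
        nxt = [pop[i] for i in elite_idx]
        while len(nxt) < params.pop_size:
            p1 = _tournament(pop, fits, rng, params.tournament_size)
            p2 = _tournament(pop, fits, rng, params.tournament_size)
            child = _crossover(p1, p2, rng) if rng.random() < params.crossover_rate else p1
            nxt.append(_mutate(child, rng, params))
        pop = nxt

    assert best is not None
    return HybridModel(
        best_chromosome=best[0],
        forecaster=best[1],
        validation_report=best[2],
        search_log=log,
    )


def ga_search(
    train_seg: TimeSeries,
    val_seg: TimeSeries,
    params: GAParams,
    train_opts: TrainOptions | None = None,
) -> HybridModel:
    """Evolve MLP configurations and return the best-ever individual.

    Runs up to ``params.max_outer_iterations`` independent GA restarts
    (sharing one evaluation cache) and keeps the restart whose best
    individual has the highest validation fitness.
    """
    train_opts = train_opts or TrainOptions()
    values = np.concatenate([train_seg.values, val_seg.values])
    train_end = len(train_seg)
    val_end = values.size
    if train_end <= params.max_lags:
        raise ValueError("training segment shorter than the maximum lag window")

    cache: dict = {}
    best: HybridModel | None = None
    ss = np.random.SeedSequence(params.seed)
    run_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(params.max_outer_iterations)]
    for run_seed in run_seeds:
        candidate = _ga_once(values, train_end, val_end, params, run_seed, train_opts, cache)
        if best is None or candidate.validation_report.fitness > best.validation_report.fitness:
            best = candidate
    assert best is not None
    return best


def phase_adjust(
    model: HybridModel, train_seg: TimeSeries, val_seg: TimeSeries
) -> HybridModel:
    """Fit y'(t) = a * y(t - phi) + b (phi in {0, 1}) on the validation
    segment; keep the adjustment only if validation fitness improves."""
    values = np.concatenate([train_seg.values, val_seg.values])
    train_end, val_end = len(train_seg), values.size
    base = model.forecaster
    raw = base.predict_series(values)
    targets = values

    best_fit = model.validation_report.fitness
    best_adj: PhaseAdjustment | None = None
    best_report = model.validation_report

    min_lag = min(base.lags)
    for phi in (0, 1):
        if phi >= min_lag:
            continue  # a forward shift would need future observations
        # raw[t + phi] must exist: t + phi in [max_lag, val_end - 1]
        start = max(train_end, base.max_lag - phi)
        idx = np.arange(start, val_end - phi)
        if idx.size < 3:
            continue  # nothing to fit
        preds_shifted = raw[idx + phi]
        t = targets[idx]
        if not np.all(np.isfinite(preds_shifted)):
            continue
        A = np.column_stack([preds_shifted, np.ones_like(preds_shifted)])
        (a, b), *_ = np.linalg.lstsq(A, t, rcond=None)
        candidate = FittedForecaster(
            base.model, base.lags, PhaseAdjustment(phi, float(a), float(b)),
            base.output_bounds, base.input_bounds,
        )
        preds = candidate.predict_series(values)
        sel = np.arange(train_end, val_end)
        sel = sel[np.isfinite(preds[sel])]
        if sel.size < 2:
            continue
        report = evaluate_all(targets[sel], preds[sel])
        if np.isfinite(report.fitness) and report.fitness > best_fit:
            best_fit, best_adj, best_report = report.fitness, candidate.adjustment, report

    if best_adj is None:
        return replace_model(model, phase_applied=False)
    adjusted = FittedForecaster(
        base.model, base.lags, best_adj, base.output_bounds, base.input_bounds
    )
    return HybridModel(
        best_chromosome=model.best_chromosome,
        forecaster=adjusted,
        validation_report=best_report,
        search_log=model.search_log,
        phase_applied=True,
    )


def replace_model(model: HybridModel, **kw) -> HybridModel:
    return HybridModel(
        best_chromosome=model.best_chromosome,
        forecaster=model.forecaster,
        validation_report=model.validation_report,
        search_log=model.search_log,
        phase_applied=kw.get("phase_applied", model.phase_applied),
    )


def fit_hybrid(
    train_seg: TimeSeries,
    val_seg: TimeSeries,
    params: GAParams,
    train_opts: TrainOptions | None = None,
) -> HybridModel:
    """GA structure search followed by the optional phase adjustment."""
    model = ga_search(train_seg, val_seg, params, train_opts)
    if params.phase_adjustment == "affine_shift":
        model = phase_adjust(model, train_seg, val_seg)
    return model
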