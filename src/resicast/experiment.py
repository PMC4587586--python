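"""The repeated-run experiment protocol around one correction chain.

Ten (by default) seeded repetitions of the full fit are run on a series;
the repetition with the best validation fitness at its selected depth is
reported.  The report carries one metrics row per cumulative stage
(uncorrected, +C1, +C2, ...), ratio rows comparing consecutive stages
and the selected stage against the uncorrected model, and the per-stage
ACF traces of the training residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .correction import (
    CorrectionChain,
    ann_correction_factory,
    fit_correction_chain,
    hybrid_base_factory,
    hybrid_correction_factory,
    mlp_base_factory,
)
from .metrics import MetricsReport, RatioReport, metric_ratio
from .series import TimeSeries, normalize_minmax, chronological_split

__all__ = ["ExperimentReport", "run_experiment"]


@dataclass
class ExperimentReport:
    """Everything a run produces, ready for rendering."""

    series_name: str
    master_seed: int
    config: dict
    repetition_seeds: list[int]
    repetition_summaries: list[dict]  # seed, selected_depth, stop_reason, val fitness
    best_repetition: int
    stage_labels: list[str]
    val_reports: list[MetricsReport]
    test_reports: list[MetricsReport]
    ratio_rows: list[tuple[str, RatioReport]]
    acf_traces: list[dict]
    selected_depth: int
    stop_reason: str
    chain: CorrectionChain = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "series_name": self.series_name,
            "master_seed": self.master_seed,
            "config": self.config,
            "repetition_seeds": self.repetition_seeds,
            "repetition_summaries": self.repetition_summaries,
            "best_repetition": self.best_repetition,
            "stage_labels": self.stage_labels,
            "val_reports": [r.as_dict() for r in self.val_reports],
            "test_reports": [r.as_dict() for r in self.test_reports],
            "ratio_rows": [[label, r.as_dict()] for label, r in self.ratio_rows],
            "acf_traces": self.acf_traces,
            "selected_depth": self.selected_depth,
            "stop_reason": self.stop_reason,
        }


def _build_factories(cfg: RunConfig):
    train_opts = cfg.train.to_options()
    if cfg.base.kind == "hybrid":
        base = hybrid_base_factory(cfg.base.hybrid.to_params(), train_opts)
    else:
        m = cfg.base.mlp
        base = mlp_base_factory(m.n_lags, m.n_hidden, m.trainer, train_opts)
    if cfg.correction.method == "ann":
        corr = ann_correction_factory(
            hidden_sweep=tuple(cfg.correction.hidden_sweep),
            max_acf_lags=cfg.correction.max_acf_lags,
            train_opts=train_opts,
            acf_bound=cfg.correction.acf.bound,
            lag_mode=cfg.correction.lag_mode,
        )
    else:
        corr = hybrid_correction_factory(cfg.correction.hybrid.to_params(), train_opts)
    return base, corr


def run_experiment(series: TimeSeries, cfg: RunConfig) -> ExperimentReport:
    """Run the repeated-fit protocol on one series and assemble the report."""
    # normalization: fitted on the full series by default, or on the
    # training segment for leak-free operation
    if cfg.normalization.fit_on == "train":
        tr, _, _ = chronological_split(series, cfg.split.to_spec())
        _, params = normalize_minmax(tr)
        norm = series.replace_values((series.values - params.low) / params.scale)
    else:
        norm, params = normalize_minmax(series)

    base, corr = _build_factories(cfg)
    policy = cfg.correction.stop.to_policy()
    metric_kw = cfg.metrics.kwargs()

    ss = np.random.SeedSequence(cfg.seed)
    rep_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(cfg.experiment.repetitions)]

    chains: list[CorrectionChain | None] = []
    summaries: list[dict] = []
    for rep_seed in rep_seeds:
        try:
            chain = fit_correction_chain(
                norm,
                base,
                corr,
                cfg.split.to_spec(),
                policy,
                seed=rep_seed,
                acf_bound=cfg.correction.acf.bound,
                acf_tolerance=cfg.correction.acf.tolerance,
                acf_max_lag=cfg.correction.acf.max_lag,
                metric_kw=metric_kw,
                selection=cfg.correction.selection,
            )
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            chains.append(None)
            summaries.append({"seed": rep_seed, "failed": str(exc)})
            continue
        chains.append(chain)
        sel = chain.selected_depth
        summaries.append(
            {
                "seed": rep_seed,
                "selected_depth": sel,
                "stop_reason": chain.stop_reason,
                "val_fitness": chain.records[sel].val_report.fitness,
            }
        )

    survivors = [i for i, c in enumerate(chains) if c is not None]
    if not survivors:
        raise RuntimeError("every repetition failed")

    if cfg.experiment.selection == "last":
        best_i = survivors[-1]
    else:
        best_i = max(
            survivors,
            key=lambda i: (
                chains[i].records[chains[i].selected_depth].val_report.fitness
                if np.isfinite(chains[i].records[chains[i].selected_depth].val_report.fitness)
                else -np.inf
            ),
        )
    chain = chains[best_i]

    # if the metric scale is "original", recompute every report on the
    # de-normalized scale
    if cfg.metrics.scale == "original":
        records = _rescale_records(chain, params, metric_kw)
    else:
        records = chain.records

    base_label = "HS" if cfg.base.kind == "hybrid" else "MLP"

    def _label(d: int) -> str:
        if d == 0:
            return base_label
        if d == 1:
            return f"{base_label}+C1"
        return f"{base_label}+C1+...+C{d}"

    labels = [_label(r.depth) for r in records]
    val_reports = [r.val_report for r in records]
    test_reports = [r.test_report for r in records]

    ratio_rows: list[tuple[str, RatioReport]] = []
    for d in range(1, len(records)):
        ratio_rows.append(
            (f"C{d}-C{d - 1}", metric_ratio(test_reports[d], test_reports[d - 1]))
        )
    if chain.selected_depth >= 1:
        ratio_rows.append(
            (
                f"C{chain.selected_depth}-C0",
                metric_ratio(test_reports[chain.selected_depth], test_reports[0]),
            )
        )

    acf_traces = [
        {"stage": r.depth, **(r.acf_result.as_dict() if r.acf_result else {})}
        for r in records
    ]

    return ExperimentReport(
        series_name=series.name,
        master_seed=cfg.seed,
        config=cfg.model_dump(),
        repetition_seeds=rep_seeds,
        repetition_summaries=summaries,
        best_repetition=best_i,
        stage_labels=labels,
        val_reports=val_reports,
        test_reports=test_reports,
        ratio_rows=ratio_rows,
        acf_traces=acf_traces,
        selected_depth=chain.selected_depth,
        stop_reason=chain.stop_reason,
        chain=chain,
    )


def _rescale_records(chain: CorrectionChain, params, metric_kw: dict):
    """Recompute stage reports on the original concentration scale."""
    from dataclasses import replace
    from .metrics import evaluate_all

    x = chain.series_values * params.scale + params.low
    out = []
    for rec in chain.records:
        combined = chain.combined_prediction(rec.depth) * params.scale + params.low

        def seg(lo, hi):
            t, p = x[lo:hi], combined[lo:hi]
            ok = np.isfinite(p)
            return evaluate_all(t[ok], p[ok], **metric_kw)

        out.append(
            replace(
                rec,
                val_report=seg(chain.train_end, chain.val_end),
                test_report=seg(chain.val_end, x.size),
            )
        )
    return out
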