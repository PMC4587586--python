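"""CSV/JSON input-output and report rendering.

Series files are single-value-column CSVs (header ``value``) with an
optional leading ISO-8601 ``date`` column.  Reports render to a metrics
CSV (one row per cumulative stage), a ratio CSV, per-stage ACF trace
CSVs, a machine-readable JSON twin, and a run log carrying the resolved
configuration and master seed for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiment import ExperimentReport
from .metrics import MetricsReport, RatioReport
from .series import TimeSeries

__all__ = ["read_series_csv", "write_series_csv", "render_reports", "ParseError"]


class ParseError(ValueError):
    """A series CSV could not be parsed; the message names the row."""


def read_series_csv(path) -> TimeSeries:
    """Read a series CSV: column ``value``, optional first column ``date``."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    if df.empty:
        raise ParseError(f"{path}: file has no data rows")
    if "value" not in df.columns:
        raise ParseError(f"{path}: missing required column 'value'")
    raw = df["value"]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() | ~np.isfinite(values.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + 2  # 1-based, plus header line
        raise ParseError(f"{path}: non-numeric or missing value at line {row}")
    timestamps = None
    if "date" in df.columns:
        try:
            ts = pd.to_datetime(df["date"], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: unparseable date column ({exc})") from exc
        timestamps = tuple(ts.dt.strftime("%Y-%m-%d"))
    return TimeSeries(values.to_numpy(dtype=float), name=path.stem, timestamps=timestamps)


def write_series_csv(series: TimeSeries, path) -> None:
    """Write a series CSV mirroring :func:`read_series_csv`."""
    path = Path(path)
    cols = {}
    if series.timestamps is not None:
        cols["date"] = list(series.timestamps)
    cols["value"] = [repr(float(v)) for v in series.values]
    pd.DataFrame(cols).to_csv(path, index=False)


# ----------------------------------------------------------------------
# report rendering
# ----------------------------------------------------------------------

_TABLE_COLUMNS = ["Model", "MSE", "POCID", "U", "MAPE", "ARV", "IA", "Fitness"]


def _metrics_row(label: str, r: MetricsReport) -> dict:
    return {
        "Model": label,
        "MSE": f"{r.mse:.2E}",
        "POCID": f"{r.pocid:.2f}",
        "U": f"{r.theil_u:.4f}",
        "MAPE": f"{r.mape:.2f}",
        "ARV": f"{r.arv:.4f}",
        "IA": f"{r.ia:.3f}",
        "Fitness": f"{r.fitness:.2f}",
    }


def _ratio_row(label: str, r: RatioReport) -> dict:
    return {
        "Model": label,
        "MSE": f"{r.mse:.3f}",
        "POCID": f"{r.pocid:.3f}",
        "U": f"{r.theil_u:.3f}",
        "MAPE": f"{r.mape:.3f}",
        "ARV": f"{r.arv:.3f}",
        "IA": f"{r.ia:.3f}",
        "Fitness": f"{r.fitness:.3f}",
    }


def render_reports(report: ExperimentReport, out_dir) -> dict[str, Path]:
    """Write metrics/ratio/ACF CSVs, the JSON twin and the run log.

    Returns a mapping of artifact name to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = [
        _metrics_row(label, rep)
        for label, rep in zip(report.stage_labels, report.test_reports)
    ]
    paths["metrics"] = out / "metrics.csv"
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(paths["metrics"], index=False)

    ratio_rows = [_ratio_row(label, r) for label, r in report.ratio_rows]
    paths["ratios"] = out / "ratios.csv"
    pd.DataFrame(ratio_rows, columns=_TABLE_COLUMNS).to_csv(paths["ratios"], index=False)

    for trace in report.acf_traces:
        if "lags" not in trace:
            continue
        p = out / f"acf_stage_{trace['stage']}.csv"
        pd.DataFrame(
            {"lag": trace["lags"], "rho": trace["rho"], "bound": trace["bound"]}
        ).to_csv(p, index=False)
        paths[f"acf_stage_{trace['stage']}"] = p

    paths["report"] = out / "report.json"
    with open(paths["report"], "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)

    paths["chain"] = out / "chain.json"
    with open(paths["chain"], "w", encoding="utf-8") as fh:
        json.dump(report.chain.to_dict(), fh, indent=2, sort_keys=True)

    paths["run_log"] = out / "run_log.json"
    log_lines = [
        {
            "stage": rec["stage"] if "stage" in rec else None,
            **rec,
        }
        for rec in report.acf_traces
    ]
    with open(paths["run_log"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "series": report.series_name,
                "master_seed": report.master_seed,
                "config": report.config,
                "repetitions": report.repetition_summaries,
                "best_repetition": report.best_repetition,
                "selected_depth": report.selected_depth,
                "stop_reason": report.stop_reason,
                "stages": log_lines,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return paths
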