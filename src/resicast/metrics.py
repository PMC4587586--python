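"""Forecast-evaluation metrics, the scalar fitness score, and metric ratios.

Six metrics are computed for every target/forecast pair: mean squared
error (MSE), mean absolute percentage error (MAPE, in percent), Theil's
U statistic, average relative variance (ARV), prediction of change in
direction (POCID, in percent) and the index of agreement (IA).  The
fitness score aggregates five of them,

    Fitness = POCID / (1 + MSE + MAPE + U + ARV),

with MAPE and POCID entering on the percent scale, so higher fitness
(closer to 100) means a more accurate forecast.  Per-metric ratios of a
corrected against an uncorrected forecaster quantify how much a
correction stage helped.

Two conventions here follow the printed forms used in the PM-forecasting
literature rather than the textbook ones and can be switched:

* Theil's U divides by summed squared successive differences of the
  *forecast* (``u_denominator="outputs"``); the classical random-walk
  comparison uses the targets (``"targets"``).
* ARV and IA measure spread of the *forecast* around the target mean in
  their denominators (``variant="printed"``); ``"classical"`` uses the
  targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "MetricsReport",
    "RatioReport",
    "MetricError",
    "mse",
    "mape",
    "theil_u",
    "arv",
    "pocid",
    "ia",
    "fitness",
    "evaluate_all",
    "metric_ratio",
]

METRIC_ORDER = ("mse", "pocid", "theil_u", "mape", "arv", "ia", "fitness")


class MetricError(ValueError):
    """A metric is undefined for the given vectors (empty, mismatched,
    zero denominator, ...)."""


def _validate(targets, outputs, min_len: int = 1) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(targets, dtype=float)
    o = np.asarray(outputs, dtype=float)
    if t.shape != o.shape or t.ndim != 1:
        raise MetricError("targets and outputs must be 1-D vectors of equal length")
    if t.size < min_len:
        raise MetricError(f"need at least {min_len} points, got {t.size}")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(o))):
        raise MetricError("targets and outputs must be finite")
    return t, o


def mse(targets, outputs) -> float:
    """Mean squared error, (1/N) * sum (target_j - output_j)^2."""
    t, o = _validate(targets, outputs)
    return float(np.mean((t - o) ** 2))


def mape(targets, outputs, epsilon: float = 1e-8) -> float:
    """Mean absolute percentage error, 100/N * sum |(t_j - o_j)/t_j|.

    Points with ``|target| < epsilon`` are excluded from the mean (the
    min-max scaled series always contains an exact zero).  Use
    :func:`mape_with_exclusions` to also retrieve the excluded count.
    """
    return mape_with_exclusions(targets, outputs, epsilon)[0]


def mape_with_exclusions(targets, outputs, epsilon: float = 1e-8) -> tuple[float, int]:
    t, o = _validate(targets, outputs)
    keep = np.abs(t) >= epsilon
    n_excluded = int(np.sum(~keep))
    if not np.any(keep):
        raise MetricError("MAPE undefined: every target is below epsilon")
    return float(100.0 * np.mean(np.abs((t[keep] - o[keep]) / t[keep]))), n_excluded


def theil_u(targets, outputs, denominator: str = "outputs") -> float:
    """Theil's U: summed squared errors over summed squared successive
    differences of the forecast (or of the targets when
    ``denominator="targets"``)."""
    t, o = _validate(targets, outputs, min_len=2)
    ref = o if denominator == "outputs" else t
    den = float(np.sum(np.diff(ref) ** 2))
    if den == 0.0:
        raise MetricError("Theil U undefined: reference series is constant")
    return float(np.sum((t - o) ** 2) / den)


def arv(targets, outputs, variant: str = "printed") -> float:
    """Average relative variance.

    ``printed`` divides by sum (output_j - mean(target))^2; ``classical``
    divides by sum (target_j - mean(target))^2.  Values below 1 beat the
    constant mean forecast.
    """
    t, o = _validate(targets, outputs)
    tbar = float(np.mean(t))
    ref = o if variant == "printed" else t
    den = float(np.sum((ref - tbar) ** 2))
    if den == 0.0:
        raise MetricError("ARV undefined: zero denominator")
    return float(np.sum((o - t) ** 2) / den)


def pocid(targets, outputs) -> float:
    """Percentage of correctly predicted directions of change.

    Steps j = 2..N count as hits when the target change and the forecast
    change have the same strict sign; ties (zero change on either side)
    count as misses.  Result is 100 * hits / (N - 1).
    """
    t, o = _validate(targets, outputs, min_len=2)
    d = np.diff(t) * np.diff(o)
    return float(100.0 * np.mean(d > 0.0))


def ia(targets, outputs, variant: str = "printed") -> float:
    """Index of agreement; 1 indicates a perfect forecast.

    IA = 1 - sum |o_j - t_j|^2 / sum (|o_j - tbar| + |t_j - tbar|)^2.
    """
    t, o = _validate(targets, outputs)
    tbar = float(np.mean(t))
    num = float(np.sum((o - t) ** 2))
    den = float(np.sum((np.abs(o - tbar) + np.abs(t - tbar)) ** 2))
    if den == 0.0:
        raise MetricError("IA undefined: zero denominator")
    return float(1.0 - num / den)


def fitness(pocid: float, mse: float, mape: float, theil_u: float, arv: float) -> float:
    """POCID / (1 + MSE + MAPE + U + ARV), POCID and MAPE on the percent scale."""
    for v in (pocid, mse, mape, theil_u, arv):
        if not math.isfinite(v) or v < 0:
            raise MetricError("fitness requires finite non-negative inputs")
    return pocid / (1.0 + mse + mape + theil_u + arv)


@dataclass(frozen=True)
class MetricsReport:
    """All six metrics plus fitness for one target/forecast pair."""

    mse: float
    pocid: float
    theil_u: float
    mape: float
    arv: float
    ia: float
    fitness: float
    n: int
    n_mape_excluded: int = 0
    flags: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        return asdict(self)

    def row(self) -> dict:
        """Ordered row matching the conventional results-table layout."""
        return {k.upper() if k != "theil_u" else "U": getattr(self, k) for k in METRIC_ORDER}


@dataclass(frozen=True)
class RatioReport:
    """Per-metric ratio corrected / uncorrected for all seven quantities.

    For POCID, IA and fitness a ratio above 1 means the correction
    helped; for MSE, U, MAPE and ARV a ratio below 1 does.  Metrics with
    a zero uncorrected value are NaN and listed in ``undefined``.
    """

    mse: float
    pocid: float
    theil_u: float
    mape: float
    arv: float
    ia: float
    fitness: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_all(
    targets,
    outputs,
    *,
    mape_epsilon: float = 1e-8,
    u_denominator: str = "outputs",
    variant: str = "printed",
) -> MetricsReport:
    """Compute every metric on one aligned pair and bundle them.

    Undefined component metrics become NaN and are listed in ``flags``
    instead of aborting the whole report; fitness is recomputed from the
    stored component values.
    """
    t, o = _validate(targets, outputs, min_len=2)
    vals: dict[str, float] = {}
    flags: list[str] = []
    n_excl = 0

    def _try(name, fn):
        nonlocal n_excl
        try:
            if name == "mape":
                v, n_excl = mape_with_exclusions(t, o, mape_epsilon)
            else:
                v = fn()
            vals[name] = v
        except MetricError:
            vals[name] = float("nan")
            flags.append(name)

    _try("mse", lambda: mse(t, o))
    _try("mape", None)
    _try("theil_u", lambda: theil_u(t, o, u_denominator))
    _try("arv", lambda: arv(t, o, variant))
    _try("pocid", lambda: pocid(t, o))
    _try("ia", lambda: ia(t, o, variant))
    try:
        fit = fitness(vals["pocid"], vals["mse"], vals["mape"], vals["theil_u"], vals["arv"])
    except MetricError:
        fit = float("nan")
        flags.append("fitness")
    return MetricsReport(
        mse=vals["mse"],
        pocid=vals["pocid"],
        theil_u=vals["theil_u"],
        mape=vals["mape"],
        arv=vals["arv"],
        ia=vals["ia"],
        fitness=fit,
        n=int(t.size),
        n_mape_excluded=n_excl,
        flags=tuple(flags),
    )


def metric_ratio(corrected: MetricsReport, uncorrected: MetricsReport) -> RatioReport:
    """Elementwise ratio corrected / uncorrected for all seven metrics."""
    out: dict[str, float] = {}
    undefined: list[str] = []
    for name in METRIC_ORDER:
        c = getattr(corrected, name)
        u = getattr(uncorrected, name)
        if u == 0.0 or not (math.isfinite(u) and math.isfinite(c)):
            out[name] = float("nan")
            undefined.append(name)
        else:
            out[name] = c / u
    return RatioReport(undefined=tuple(undefined), **out)
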