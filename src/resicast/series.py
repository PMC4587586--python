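"""Time-series container, min-max scaling, chronological splits and lag windows.

Every stage of the forecasting pipeline consumes and produces a
:class:`TimeSeries`.  The helpers here are deliberately dumb: they carry
timestamps along but never use them in any computation, and they never
impute gaps -- missing-data handling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "NormalizationParams",
    "SplitSpec",
    "SupervisedWindowSet",
    "normalize_minmax",
    "denormalize",
    "chronological_split",
    "make_lag_matrix",
    "DegenerateScaleError",
    "SplitError",
    "InsufficientDataError",
]


class DegenerateScaleError(ValueError):
    """Raised when min-max scaling is requested on a constant series."""


class SplitError(ValueError):
    """Raised when a chronological split would produce an empty segment."""


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested lag window."""


@dataclass(frozen=True)
class TimeSeries:
    """Ordered real-valued observations with optional date labels.

    Parameters
    ----------
    values
        The observations, oldest first.  Must be finite.
    name
        Free-text label (e.g. ``"kallio_pm25"``).
    timestamps
        Optional ordered labels, one per value, strictly increasing.
    """

    values: np.ndarray
    name: str = "series"
    timestamps: tuple | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if arr.size < 1:
            raise ValueError("series must contain at least one value")
        if not np.all(np.isfinite(arr)):
            raise ValueError("series values must be finite (no NaN/Inf)")
        object.__setattr__(self, "values", arr)
        if self.timestamps is not None:
            ts = tuple(self.timestamps)
            if len(ts) != arr.size:
                raise ValueError("timestamps must match values in length")
            if any(a >= b for a, b in zip(ts, ts[1:])):
                raise ValueError("timestamps must be strictly increasing")
            object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return int(self.values.size)

    def replace_values(self, values: np.ndarray, name: str | None = None) -> "TimeSeries":
        """New series with the same metadata but different values."""
        ts = self.timestamps if len(values) == len(self) else None
        return TimeSeries(np.asarray(values, dtype=float), name or self.name, ts)


@dataclass(frozen=True)
class NormalizationParams:
    """Affine min-max scaling parameters: x -> (x - low) / (high - low)."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ValueError("normalization bounds must be finite")
        if self.high <= self.low:
            raise DegenerateScaleError(
                f"high ({self.high}) must exceed low ({self.low})"
            )

    @property
    def scale(self) -> float:
        return self.high - self.low


@dataclass(frozen=True)
class SplitSpec:
    """Chronological train/validation/test proportions."""

    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1

    def __post_init__(self) -> None:
        for f in (self.train_frac, self.val_frac, self.test_frac):
            if not (0.0 < f < 1.0):
                raise ValueError("split fractions must lie in (0, 1)")
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class SupervisedWindowSet:
    """Lagged input matrix plus one-step-ahead targets.

    Row ``i`` holds the series values at offsets ``t - k`` for each lag
    ``k`` in ``lags`` (largest lag first, i.e. oldest to newest) and the
    target is the value at ``t``, where ``t = max(lags) + i``.
    """

    inputs: np.ndarray
    targets: np.ndarray
    lags: tuple[int, ...]
    target_indices: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError("inputs and targets must have equal row counts")

    @property
    def n_rows(self) -> int:
        return int(self.targets.size)

    @property
    def max_lag(self) -> int:
        return max(self.lags)


def normalize_minmax(
    series: TimeSeries, params: NormalizationParams | None = None
) -> tuple[TimeSeries, NormalizationParams]:
    """Scale a series onto [0, 1] by its (or supplied) min and max.

    When ``params`` is omitted they are fitted from the full series, so
    the minimum maps to 0 and the maximum to 1.  The returned parameters
    invert the transform exactly via :func:`denormalize`.
    """
    x = series.values
    if params is None:
        if len(series) < 2:
            raise ValueError("need at least two points to fit scaling parameters")
        low, high = float(np.min(x)), float(np.max(x))
        if high == low:
            raise DegenerateScaleError("constant series has zero range")
        params = NormalizationParams(low, high)
    scaled = (x - params.low) / params.scale
    return series.replace_values(scaled), params


def denormalize(series: TimeSeries, params: NormalizationParams) -> TimeSeries:
    """Invert :func:`normalize_minmax`: x -> x * (high - low) + low."""
    return series.replace_values(series.values * params.scale + params.low)


def chronological_split(
    series: TimeSeries, spec: SplitSpec
) -> tuple[TimeSeries, TimeSeries, TimeSeries]:
    """Split into contiguous train/validation/test segments, in time order.

    Boundaries fall at ``floor(N * train_frac)`` and
    ``floor(N * (train_frac + val_frac))``; any rounding remainder is
    absorbed by the test segment.
    """
    n = len(series)
    i1 = int(np.floor(n * spec.train_frac))
    i2 = int(np.floor(n * (spec.train_frac + spec.val_frac)))
    if i1 < 1 or i2 - i1 < 1 or n - i2 < 1:
        raise SplitError(f"split {spec} on length {n} yields an empty segment")

    def _seg(a: int, b: int, tag: str) -> TimeSeries:
        ts = series.timestamps[a:b] if series.timestamps is not None else None
        return TimeSeries(series.values[a:b], f"{series.name}/{tag}", ts)

    return _seg(0, i1, "train"), _seg(i1, i2, "val"), _seg(i2, n, "test")


def _resolve_lags(lag_spec: int | Sequence[int]) -> tuple[int, ...]:
    if isinstance(lag_spec, (int, np.integer)):
        if lag_spec < 1:
            raise ValueError("lag count must be >= 1")
        return tuple(range(int(lag_spec), 0, -1))
    lags = sorted({int(k) for k in lag_spec}, reverse=True)
    if not lags or lags[-1] < 1:
        raise ValueError("lag set must contain positive lags")
    return tuple(lags)


def make_lag_matrix(
    series: TimeSeries | np.ndarray, lag_spec: int | Sequence[int]
) -> SupervisedWindowSet:
    """Build the supervised one-step-ahead set from a series.

    ``lag_spec`` is either a count ``L`` (consecutive lags 1..L) or an
    explicit set of lag offsets.  Input columns are ordered oldest to
    newest (largest lag first).
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    lags = _resolve_lags(lag_spec)
    m = lags[0]
    n = x.size
    if n <= m:
        raise InsufficientDataError(
            f"series of length {n} has no complete window for max lag {m}"
        )
    t_idx = np.arange(m, n)
    inputs = np.column_stack([x[t_idx - k] for k in lags])
    return SupervisedWindowSet(inputs, x[t_idx], lags, t_idx)
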