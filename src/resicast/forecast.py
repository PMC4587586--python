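"""Fitted lag-window forecaster: the unit every chain stage is made of.

A :class:`FittedForecaster` couples a trained MLP with its lag
specification and an optional phase adjustment, and knows how to produce
aligned one-step-ahead predictions over a series (causally: the
prediction for index ``t`` uses values strictly before ``t``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mlp import MLPModel, forward
from .series import InsufficientDataError

__all__ = ["PhaseAdjustment", "FittedForecaster"]


@dataclass(frozen=True)
class PhaseAdjustment:
    """Affine-plus-realignment correction y'(t) = a * y_raw(t + phi) + b.

    A forecaster that lags behind the series (its output tracks the
    target with a one-step delay) is realigned by reading its raw output
    one step ahead.  This stays causal only when every input lag exceeds
    ``phi`` -- the raw output at t + phi then uses observations up to
    t - 1 at most -- which the fitting routine checks before offering
    phi = 1.
    """

    phi: int
    a: float
    b: float

    def as_dict(self) -> dict:
        return {"phi": self.phi, "a": self.a, "b": self.b}


@dataclass
class FittedForecaster:
    """Trained MLP + lag offsets (+ optional phase adjustment).

    ``output_bounds``, when set, clamp every prediction to the stated
    interval (factories use the range of the training targets).  This is
    an extrapolation guard: a sigmoid network driven outside the input
    hull it was fitted on can produce arbitrarily large outputs, and a
    forecaster has no business predicting outside the target range it
    was trained against.
    """

    model: MLPModel
    lags: tuple[int, ...]  # largest first, matching input column order
    adjustment: PhaseAdjustment | None = None
    output_bounds: tuple[float, float] | None = None
    input_bounds: tuple[np.ndarray, np.ndarray] | None = None

    def _clip(self, y):
        if self.output_bounds is None:
            return y
        lo, hi = self.output_bounds
        return np.clip(y, lo, hi)

    def _clip_inputs(self, X: np.ndarray) -> np.ndarray:
        # winsorize each lag column at its training range so the network
        # is never evaluated outside the input hull it was fitted on
        if self.input_bounds is None:
            return X
        lo, hi = self.input_bounds
        return np.clip(X, lo, hi)

    @property
    def max_lag(self) -> int:
        return max(self.lags)

    @property
    def min_history(self) -> int:
        """Shortest history that allows a next-step prediction."""
        phi = self.adjustment.phi if self.adjustment else 0
        return self.max_lag - phi

    def _raw_at(self, values: np.ndarray, t: int) -> float:
        """Raw model prediction for index t (t may run past the end of
        the history as long as every required lag is available)."""
        if t < self.max_lag or t - min(self.lags) >= values.size:
            raise InsufficientDataError(
                f"prediction at index {t} needs lags {self.lags} within the history"
            )
        window = self._clip_inputs(np.array([[values[t - k] for k in self.lags]]))
        return float(self._clip(forward(self.model, window))[0])

    def predict_series(self, values: np.ndarray) -> np.ndarray:
        """Aligned predictions; indices without a full window are NaN."""
        values = np.asarray(values, dtype=float)
        n = values.size
        out = np.full(n, np.nan)
        m = self.max_lag
        if n <= m:
            return out
        t_idx = np.arange(m, n)
        X = self._clip_inputs(np.column_stack([values[t_idx - k] for k in self.lags]))
        raw = self._clip(forward(self.model, X))
        if self.adjustment is None:
            out[m:] = raw
            return out
        adj = self.adjustment
        # adjusted prediction at t reads the raw prediction at t + phi;
        # raw[j] is aligned to target index m + j
        start = max(m - adj.phi, 0)
        end = n - adj.phi
        out[start:end] = adj.a * raw[start + adj.phi - m : end + adj.phi - m] + adj.b
        return out

    def predict_next(self, values: np.ndarray) -> float:
        """One-step-ahead prediction for the index just past the history."""
        values = np.asarray(values, dtype=float)
        t = values.size
        if t < self.min_history:
            raise InsufficientDataError(
                f"history of length {t} too short (need {self.min_history})"
            )
        if self.adjustment is None:
            return self._raw_at(values, t)
        adj = self.adjustment
        return adj.a * self._raw_at(values, t + adj.phi) + adj.b

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "lags": list(self.lags),
            "adjustment": self.adjustment.as_dict() if self.adjustment else None,
            "output_bounds": list(self.output_bounds) if self.output_bounds else None,
            "input_bounds": (
                [self.input_bounds[0].tolist(), self.input_bounds[1].tolist()]
                if self.input_bounds
                else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedForecaster":
        adj = d.get("adjustment")
        ob = d.get("output_bounds")
        ib = d.get("input_bounds")
        return cls(
            model=MLPModel.from_dict(d["model"]),
            lags=tuple(int(k) for k in d["lags"]),
            adjustment=PhaseAdjustment(**adj) if adj else None,
            output_bounds=(float(ob[0]), float(ob[1])) if ob else None,
            input_bounds=(np.asarray(ib[0]), np.asarray(ib[1])) if ib else None,
        )
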