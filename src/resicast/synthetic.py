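"""Seeded generators for series with the structure the method assumes.

Real daily particulate-matter (PM2.5/PM10) concentration series are
positive, right-skewed, and carry autocorrelated linear structure mixed
with nonlinear patterns and noise.  The generators here emulate those
features so every stage of the pipeline is testable without external
data:

* :func:`gen_white_noise` -- i.i.d. Gaussian shocks (the stopping
  condition of the correction loop).
* :func:`gen_ar` -- a stationary AR(p) with Gaussian innovations (the
  linear structure a base forecaster should capture).
* :func:`gen_composite` -- linear AR part + a nonlinear component +
  white noise, with the three components returned separately and
  summing exactly to the series.  The default settings (AR(2) with
  coefficients 0.6, -0.2; a sinusoid-modulated nonlinear term at half
  the linear part's standard deviation; noise at a signal-to-noise
  variance ratio of 5) are chosen so that a deliberately weak base
  forecaster under-fits and leaves forecastable structure in its
  residuals.
* :func:`gen_pm_like` -- exp of a seasonal AR Gaussian process scaled
  to a typical daily-mean concentration range: strictly positive,
  right-skewed, autocorrelated.

All generators are bitwise-reproducible under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .series import TimeSeries

__all__ = [
    "SyntheticBundle",
    "gen_white_noise",
    "gen_ar",
    "gen_composite",
    "gen_pm_like",
    "NONLINEAR_FORMS",
]

NONLINEAR_FORMS = ("threshold_ar", "sinusoid", "quadratic")

DEFAULT_AR_COEFFS = (0.6, -0.2)
DEFAULT_NONLINEAR_AMPLITUDE_FRAC = 0.5  # x sd(linear part)
DEFAULT_SNR = 5.0  # var(signal) / var(noise)
DEFAULT_SIN_PERIOD = 7.0  # weekly cycle, as in daily pollution series


@dataclass(frozen=True)
class SyntheticBundle:
    """A composite series and its generating components.

    ``linear + nonlinear + noise == series.values`` exactly.
    """

    series: TimeSeries
    linear: np.ndarray
    nonlinear: np.ndarray
    noise: np.ndarray
    spec: dict = field(default_factory=dict)


def gen_white_noise(n: int, sigma: float = 1.0, seed: int = 0) -> TimeSeries:
    """i.i.d. zero-mean Gaussian draws."""
    if n < 1 or sigma <= 0:
        raise ValueError("need n >= 1 and sigma > 0")
    rng = np.random.default_rng(seed)
    return TimeSeries(rng.normal(0.0, sigma, size=n), name=f"white_noise[{seed}]")


def _check_stationary(coeffs: np.ndarray) -> None:
    p = coeffs.size
    companion = np.zeros((p, p))
    companion[0, :] = coeffs
    if p > 1:
        companion[1:, :-1] = np.eye(p - 1)
    if np.max(np.abs(np.linalg.eigvals(companion))) >= 1.0:
        raise ValueError(f"AR coefficients {coeffs.tolist()} are not stationary")


def _ar_path(coeffs: np.ndarray, innovations: np.ndarray) -> np.ndarray:
    p = coeffs.size
    x = np.zeros(innovations.size)
    for t in range(innovations.size):
        past = x[max(0, t - p) : t][::-1]
        x[t] = float(coeffs[: past.size] @ past) + innovations[t]
    return x


def gen_ar(
    n: int, coeffs: Sequence[float] = DEFAULT_AR_COEFFS, sigma: float = 1.0, seed: int = 0
) -> TimeSeries:
    """Stationary AR(p) recursion; a burn-in of 10*p draws is discarded."""
    if n < 1 or sigma <= 0:
        raise ValueError("need n >= 1 and sigma > 0")
    c = np.asarray(coeffs, dtype=float)
    _check_stationary(c)
    burn = 10 * c.size
    rng = np.random.default_rng(seed)
    x = _ar_path(c, rng.normal(0.0, sigma, size=n + burn))
    return TimeSeries(x[burn:], name=f"ar{c.size}[{seed}]")


def _nonlinear_component(
    form: str, linear: np.ndarray, amplitude: float, period: float
) -> np.ndarray:
    """Nonlinear component, rescaled so its standard deviation equals
    ``amplitude`` (the raw forms have arbitrary scale).

    ``threshold_ar`` is a regime-switching autoregressive term with
    delay 2 (the response to the linear part two steps back is steeper
    above zero than below); ``sinusoid`` is a sinusoidally modulated
    autoregressive term (a time-varying lag-1 coefficient with the given
    period); ``quadratic`` is a centered quadratic lag term.
    """
    t = np.arange(linear.size, dtype=float)
    lag1 = np.concatenate([[0.0], linear[:-1]])
    lag2 = np.concatenate([[0.0, 0.0], linear[:-2]])
    if form == "threshold_ar":
        raw = np.where(lag2 > 0.0, lag2, 0.25 * lag2)
        raw = raw - raw.mean()
    elif form == "sinusoid":
        raw = np.sin(2.0 * np.pi * t / period) * lag1
    elif form == "quadratic":
        raw = lag1 * lag1 - float(np.mean(lag1 * lag1))
    else:
        raise ValueError(f"unknown nonlinear form {form!r}; choose from {NONLINEAR_FORMS}")
    sd = float(np.std(raw))
    if sd == 0.0:
        return np.zeros_like(raw)
    return amplitude * raw / sd


def gen_composite(
    n: int,
    ar_coeffs: Sequence[float] = DEFAULT_AR_COEFFS,
    nonlinear_form: str = "threshold_ar",
    nonlinear_amplitude: float | None = None,
    noise_sigma: float | None = None,
    seed: int = 0,
    sin_period: float = DEFAULT_SIN_PERIOD,
) -> SyntheticBundle:
    """Linear AR + nonlinear component + white noise, components kept.

    ``nonlinear_amplitude`` defaults to half the standard deviation of
    the linear part; ``noise_sigma`` defaults to the value giving a
    signal-to-noise variance ratio of 5 against linear + nonlinear.
    """
    if n < 10:
        raise ValueError("composite generator needs n >= 10")
    c = np.asarray(ar_coeffs, dtype=float)
    _check_stationary(c)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2)

    linear = gen_ar(n, c, sigma=1.0, seed=int(seeds[0])).values
    amp = (
        nonlinear_amplitude
        if nonlinear_amplitude is not None
        else DEFAULT_NONLINEAR_AMPLITUDE_FRAC * float(np.std(linear))
    )
    nonlinear = _nonlinear_component(nonlinear_form, linear, amp, sin_period)
    signal = linear + nonlinear
    sig = (
        noise_sigma
        if noise_sigma is not None
        else float(np.std(signal)) / np.sqrt(DEFAULT_SNR)
    )
    noise = (
        gen_white_noise(n, sig, seed=int(seeds[1])).values if sig > 0 else np.zeros(n)
    )
    series = TimeSeries(signal + noise, name=f"composite[{seed}]")
    spec = {
        "n": n,
        "ar_coeffs": c.tolist(),
        "nonlinear_form": nonlinear_form,
        "nonlinear_amplitude": amp,
        "noise_sigma": sig,
        "sin_period": sin_period,
        "seed": seed,
    }
    return SyntheticBundle(series, linear, nonlinear, noise, spec)


def gen_pm_like(n: int, seed: int = 0) -> TimeSeries:
    """Positive, right-skewed, autocorrelated daily-concentration series.

    Built as exp(mu + seasonal + AR(1) Gaussian), scaled so the median
    sits near a typical daily-mean PM10 level (~15 ug/m3).
    """
    if n < 30:
        raise ValueError("gen_pm_like needs n >= 30")
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)
    seasonal = 0.15 * np.sin(2.0 * np.pi * t / 365.25)
    u = _ar_path(np.array([0.7]), rng.normal(0.0, 0.4, size=n + 10))[10:]
    log_level = np.log(15.0) + seasonal + u
    return TimeSeries(np.exp(log_level), name=f"pm_like[{seed}]")
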