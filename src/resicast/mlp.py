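"""Single-hidden-layer MLP forecaster with four batch trainers.

The network maps a lag window to a one-step-ahead prediction:

    y = psi( W2 . phi(W1 x + b1) + b2 )

with a logistic-sigmoid hidden layer and, by default, a linear output
(the series is min-max scaled to [0, 1], and a linear output avoids
saturation at the range edges).  Four full-batch trainers are available:

* ``lm``    -- Levenberg-Marquardt (damped Gauss-Newton on the Jacobian)
* ``scg``   -- scaled conjugate gradient (Moller's parameterization)
* ``rprop`` -- resilient backpropagation (eta+ 1.2, eta- 0.5, step
  bounds [1e-6, 50], initial step 0.1)
* ``oss``   -- one-step-secant quasi-Newton with a backtracking line
  search

Training monitors a validation set every iteration and returns the
weight snapshot with the lowest validation error seen (generalization-
loss early stopping: stop once the current validation error exceeds the
best-so-far by a configured percentage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import SupervisedWindowSet

__all__ = [
    "MLPConfig",
    "TrainOptions",
    "MLPModel",
    "TRAINERS",
    "init_model",
    "forward",
    "train",
]

TRAINERS = ("lm", "scg", "rprop", "oss")
_ACTIVATIONS = ("logistic", "tanh", "identity")


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    if name == "tanh":
        return np.tanh(z)
    return z


def _act_deriv(name: str, a: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation value a = phi(z)
    if name == "logistic":
        return a * (1.0 - a)
    if name == "tanh":
        return 1.0 - a * a
    return np.ones_like(a)


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and trainer choice for one forecaster."""

    n_inputs: int
    n_hidden: int
    trainer: str = "lm"
    hidden_activation: str = "logistic"
    output_activation: str = "identity"
    seed: int = 0
    max_hidden: int = 20

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if not (1 <= self.n_hidden <= self.max_hidden):
            raise ValueError(f"n_hidden must be in [1, {self.max_hidden}]")
        if self.trainer not in TRAINERS:
            raise ValueError(f"trainer must be one of {TRAINERS}")
        if self.hidden_activation not in _ACTIVATIONS or self.output_activation not in _ACTIVATIONS:
            raise ValueError(f"activations must be one of {_ACTIVATIONS}")


@dataclass(frozen=True)
class TrainOptions:
    """Stopping rules shared by all four trainers.

    ``generalization_loss_pct`` is the early-stopping threshold: training
    halts once the current validation error exceeds the best validation
    error seen so far by more than this percentage.  ``min_progress`` is
    the minimum decrease of the training error over a sliding window of
    ``progress_window`` iterations.
    """

    max_iterations: int = 1000
    generalization_loss_pct: float = 5.0
    min_progress: float = 1e-6
    progress_window: int = 5

    def __post_init__(self) -> None:
        if self.max_iterations < 1 or self.generalization_loss_pct <= 0 or self.min_progress <= 0:
            raise ValueError("all training options must be positive")


@dataclass
class MLPModel:
    """A (possibly trained) network: config, weights and training log."""

    config: MLPConfig
    w1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    training_log: list = field(default_factory=list)  # (iter, train_mse, val_mse)
    stop_reason: str | None = None
    diverged: bool = False

    # -- parameter vector plumbing -------------------------------------
    def get_params(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2, [self.b2]])

    def set_params(self, p: np.ndarray) -> None:
        h, d = self.config.n_hidden, self.config.n_inputs
        self.w1 = p[: h * d].reshape(h, d).copy()
        self.b1 = p[h * d : h * d + h].copy()
        self.w2 = p[h * d + h : h * d + 2 * h].copy()
        self.b2 = float(p[-1])

    @property
    def n_params(self) -> int:
        h, d = self.config.n_hidden, self.config.n_inputs
        return h * d + 2 * h + 1

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": {
                "n_inputs": self.config.n_inputs,
                "n_hidden": self.config.n_hidden,
                "trainer": self.config.trainer,
                "hidden_activation": self.config.hidden_activation,
                "output_activation": self.config.output_activation,
                "seed": self.config.seed,
                "max_hidden": self.config.max_hidden,
            },
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "stop_reason": self.stop_reason,
            "diverged": self.diverged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        cfg = MLPConfig(**d["config"])
        return cls(
            config=cfg,
            w1=np.asarray(d["w1"], float),
            b1=np.asarray(d["b1"], float),
            w2=np.asarray(d["w2"], float),
            b2=float(d["b2"]),
            stop_reason=d.get("stop_reason"),
            diverged=bool(d.get("diverged", False)),
        )


def init_model(config: MLPConfig) -> MLPModel:
    """Seeded initial weights, uniform in [-0.5, 0.5] scaled by 1/sqrt(fan-in)."""
    rng = np.random.default_rng(config.seed)
    d, h = config.n_inputs, config.n_hidden
    w1 = rng.uniform(-0.5, 0.5, size=(h, d)) / np.sqrt(d)
    b1 = rng.uniform(-0.5, 0.5, size=h) / np.sqrt(d)
    w2 = rng.uniform(-0.5, 0.5, size=h) / np.sqrt(h)
    b2 = float(rng.uniform(-0.5, 0.5)) / np.sqrt(h)
    return MLPModel(config=config, w1=w1, b1=b1, w2=w2, b2=b2)


def forward(model: MLPModel, input_rows: np.ndarray) -> np.ndarray:
    """One prediction per input row (deterministic)."""
    X = np.atleast_2d(np.asarray(input_rows, float))
    if X.shape[1] != model.config.n_inputs:
        raise ValueError(
            f"input width {X.shape[1]} does not match config ({model.config.n_inputs})"
        )
    hidden = _act(model.config.hidden_activation, X @ model.w1.T + model.b1)
    return _act(model.config.output_activation, hidden @ model.w2 + model.b2)


# ----------------------------------------------------------------------
# loss, gradient, Jacobian (full batch, exact)
# ----------------------------------------------------------------------


def _residual_jacobian(model: MLPModel, X: np.ndarray, t: np.ndarray):
    """Residuals r = y - t and the Jacobian dy/dparams (rows = samples)."""
    cfg = model.config
    hidden = _act(cfg.hidden_activation, X @ model.w1.T + model.b1)  # (n, h)
    pre_out = hidden @ model.w2 + model.b2
    y = _act(cfg.output_activation, pre_out)
    psi_prime = _act_deriv(cfg.output_activation, y)  # (n,)
    r = y - t

    g = (model.w2 * _act_deriv(cfg.hidden_activation, hidden)) * psi_prime[:, None]  # (n, h)
    j_w1 = (g[:, :, None] * X[:, None, :]).reshape(X.shape[0], -1)
    j_b1 = g
    j_w2 = hidden * psi_prime[:, None]
    j_b2 = psi_prime[:, None]
    return r, np.hstack([j_w1, j_b1, j_w2, j_b2])


def _mse_loss(model: MLPModel, X: np.ndarray, t: np.ndarray) -> float:
    return float(np.mean((forward(model, X) - t) ** 2))


def _mse_grad(model: MLPModel, X: np.ndarray, t: np.ndarray) -> np.ndarray:
    r, J = _residual_jacobian(model, X, t)
    return (2.0 / X.shape[0]) * (J.T @ r)


# ----------------------------------------------------------------------
# trainers: each is a stateful object with a .step() that updates the
# model parameters in place and returns False when it can make no
# further progress
# ----------------------------------------------------------------------


class _LM:
    """Damped Gauss-Newton.  lambda shrinks on accepted steps, grows on
    rejected ones; gives up when lambda explodes."""

    def __init__(self, model, X, t):
        self.model, self.X, self.t = model, X, t
        self.lam = 1e-3

    def step(self) -> bool:
        r, J = _residual_jacobian(self.model, self.X, self.t)
        sse = float(r @ r)
        A = J.T @ J
        g = J.T @ r
        p0 = self.model.get_params()
        for _ in range(15):
            try:
                delta = np.linalg.solve(A + self.lam * np.eye(A.shape[0]), -g)
            except np.linalg.LinAlgError:
                self.lam *= 10.0
                continue
            self.model.set_params(p0 + delta)
            new_r = forward(self.model, self.X) - self.t
            new_sse = float(new_r @ new_r)
            if np.isfinite(new_sse) and new_sse < sse:
                self.lam = max(self.lam * 0.3, 1e-12)
                return True
            self.lam *= 10.0
        self.model.set_params(p0)
        return False


class _RPROP:
    ETA_PLUS, ETA_MINUS = 1.2, 0.5
    DELTA0, DELTA_MIN, DELTA_MAX = 0.1, 1e-6, 50.0

    def __init__(self, model, X, t):
        self.model, self.X, self.t = model, X, t
        self.delta = np.full(model.n_params, self.DELTA0)
        self.prev_grad = np.zeros(model.n_params)

    def step(self) -> bool:
        g = _mse_grad(self.model, self.X, self.t)
        sign_change = self.prev_grad * g
        self.delta = np.where(
            sign_change > 0,
            np.minimum(self.delta * self.ETA_PLUS, self.DELTA_MAX),
            np.where(sign_change < 0, np.maximum(self.delta * self.ETA_MINUS, self.DELTA_MIN), self.delta),
        )
        g_eff = np.where(sign_change < 0, 0.0, g)
        self.model.set_params(self.model.get_params() - np.sign(g_eff) * self.delta)
        self.prev_grad = g_eff
        return True


class _SCG:
    """Moller's scaled conjugate gradient on the mean-squared-error loss."""

    SIGMA0 = 5e-5

    def __init__(self, model, X, t):
        self.model, self.X, self.t = model, X, t
        self.lam = 5e-7
        self.lam_bar = 0.0
        self.p = None  # search direction
        self.r = None  # negative gradient
        self.success = True

    def step(self) -> bool:
        m, X, t = self.model, self.X, self.t
        w = m.get_params()
        n = w.size
        if self.p is None:
            self.r = -_mse_grad(m, X, t)
            self.p = self.r.copy()

        p_norm2 = float(self.p @ self.p)
        if p_norm2 < 1e-30:
            return False

        if self.success:
            sigma = self.SIGMA0 / np.sqrt(p_norm2)
            m.set_params(w + sigma * self.p)
            g_plus = _mse_grad(m, X, t)
            m.set_params(w)
            g_now = -self.r
            self.s = (g_plus - g_now) / sigma
            self.delta = float(self.p @ self.s)

        # scale the local curvature
        delta = self.delta + (self.lam - self.lam_bar) * p_norm2
        if delta <= 0:  # make the Hessian approximation positive definite
            self.lam_bar = 2.0 * (self.lam - delta / p_norm2)
            delta = -delta + self.lam * p_norm2
            self.lam = self.lam_bar
        mu = float(self.p @ self.r)
        alpha = mu / delta

        e_old = _mse_loss(m, X, t)
        m.set_params(w + alpha * self.p)
        e_new = _mse_loss(m, X, t)
        comp = 2.0 * delta * (e_old - e_new) / (mu * mu) if mu != 0 else -1.0

        if np.isfinite(e_new) and comp >= 0:
            self.success = True
            self.lam_bar = 0.0
            r_new = -_mse_grad(m, X, t)
            beta = (float(r_new @ r_new) - float(r_new @ self.r)) / mu if mu != 0 else 0.0
            self.r = r_new
            self.p = self.r + beta * self.p
            if comp >= 0.75:
                self.lam = max(self.lam * 0.25, 1e-15)
        else:
            m.set_params(w)
            self.success = False
            self.lam_bar = self.lam
        if comp < 0.25:
            self.lam = min(self.lam + delta * (1 - comp) / p_norm2, 1e15)
        return True


class _OSS:
    """One-step secant direction with a backtracking line search."""

    def __init__(self, model, X, t):
        self.model, self.X, self.t = model, X, t
        self.prev_g = None
        self.prev_step = None
        self.alpha0 = 1.0

    def _direction(self, g: np.ndarray) -> np.ndarray:
        if self.prev_step is None:
            return -g
        s, y = self.prev_step, g - self.prev_g
        sy = float(s @ y)
        if abs(sy) < 1e-30:
            return -g
        b = float(s @ g) / sy
        a = -(1.0 + float(y @ y) / sy) * b + float(y @ g) / sy
        return -g + a * s + b * y

    def step(self) -> bool:
        m, X, t = self.model, self.X, self.t
        g = _mse_grad(m, X, t)
        d = self._direction(g)
        if float(d @ g) >= 0:  # not a descent direction; restart
            d = -g
        w = m.get_params()
        e0 = _mse_loss(m, X, t)
        alpha = self.alpha0
        for _ in range(30):
            m.set_params(w + alpha * d)
            if np.isfinite(e_new := _mse_loss(m, X, t)) and e_new < e0:
                self.prev_g, self.prev_step = g, alpha * d
                self.alpha0 = min(alpha * 2.0, 1e3)
                return True
            alpha *= 0.5
        m.set_params(w)
        return False


_TRAINER_CLASSES = {"lm": _LM, "scg": _SCG, "rprop": _RPROP, "oss": _OSS}


def train(
    model: MLPModel,
    train_set: SupervisedWindowSet,
    val_set: SupervisedWindowSet,
    opts: TrainOptions | None = None,
) -> MLPModel:
    """Full-batch training with validation-based early stopping.

    Returns a new model holding the weight snapshot with the lowest
    validation error observed.  Stops on (i) the iteration cap, (ii) a
    generalization loss above ``opts.generalization_loss_pct`` percent,
    (iii) training-error progress below ``opts.min_progress`` over the
    progress window, or (iv) trainer stagnation / divergence (the best
    snapshot is restored and ``diverged`` flagged).
    """
    opts = opts or TrainOptions()
    if train_set.n_rows == 0 or val_set.n_rows == 0:
        raise ValueError("training and validation sets must be non-empty")

    m = MLPModel(
        config=model.config,
        w1=model.w1.copy(),
        b1=model.b1.copy(),
        w2=model.w2.copy(),
        b2=model.b2,
    )
    Xtr, ttr = train_set.inputs, train_set.targets
    Xva, tva = val_set.inputs, val_set.targets
    stepper = _TRAINER_CLASSES[m.config.trainer](m, Xtr, ttr)

    log: list[tuple[int, float, float]] = []
    best_val = np.inf
    best_params = m.get_params()
    train_hist: list[float] = []
    stop = "max_iterations"
    diverged = False

    for it in range(opts.max_iterations + 1):
        e_tr = _mse_loss(m, Xtr, ttr)
        e_va = _mse_loss(m, Xva, tva)
        if not (np.isfinite(e_tr) and np.isfinite(e_va)):
            stop, diverged = "diverged", True
            break
        log.append((it, e_tr, e_va))
        if e_va < best_val:
            best_val = e_va
            best_params = m.get_params()
        gl = 100.0 * (e_va / best_val - 1.0) if best_val > 0 else 0.0
        if gl > opts.generalization_loss_pct:
            stop = "generalization_loss"
            break
        train_hist.append(e_tr)
        if len(train_hist) > opts.progress_window:
            window_progress = train_hist[-opts.progress_window - 1] - min(
                train_hist[-opts.progress_window :]
            )
            if window_progress < opts.min_progress:
                stop = "min_progress"
                break
        if it == opts.max_iterations:
            break
        if not stepper.step():
            stop = "trainer_stagnated"
            break

    m.set_params(best_params)
    m.training_log = log
    m.stop_reason = stop
    m.diverged = diverged
    return m
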