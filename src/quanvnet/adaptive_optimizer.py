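"""Loss-adaptive momentum SGD.

The "fully adaptive" scheme couples two per-epoch adaptations:

* a geometric learning-rate decay, lr(epoch) = initial_lr * lr_decay**epoch;
* a loss-driven momentum, alpha = beta / (1 - exp(-(loss_t + loss_{t-1}))),
  clamped to ``momentum_cap``, with a fixed default momentum for the first
  two epochs (before two loss evaluations exist).

With beta = 1 the raw momentum exceeds 1 for every finite positive loss sum
(the denominator is < 1), so the cap binds and momentum sits at the cap
until losses diverge; for beta < 1 the momentum tends to beta as the summed
loss grows.  Weight updates follow the classical heavy-ball rule: velocity
accumulates the negative gradient scaled by the learning rate, plus the
momentum-scaled previous velocity.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass(frozen=True)
class OptimizerConfig:
    """Hyperparameters of the adaptive schedule.

    initial_lr       starting learning rate (epoch 0)
    lr_decay         per-epoch geometric decay factor, in (0, 1)
    beta             numerator constant of the adaptive momentum, in (0, 1]
    momentum_cap     upper clamp on the adaptive momentum, in (0, 1)
    default_momentum momentum used for the first two epochs
    """

    initial_lr: float = 0.01
    lr_decay: float = 0.1
    beta: float = 1.0
    momentum_cap: float = 0.999
    default_momentum: float = 0.9

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0.0 < self.lr_decay < 1.0:
            raise ValueError("lr_decay must lie in (0, 1)")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        if not 0.0 < self.momentum_cap < 1.0:
            raise ValueError("momentum_cap must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "OptimizerConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    @classmethod
    def from_yaml(cls, path) -> "OptimizerConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


@dataclass
class OptimizerState:
    """Mutable per-run state: epoch counter, loss history, velocity buffer,
    and the schedule values currently in force."""

    epoch: int = 0
    loss_history: list[float] = field(default_factory=list)
    velocity: np.ndarray | None = None
    current_lr: float = 0.01
    current_momentum: float = 0.9


def calculate_momentum(
    loss_t: float, loss_prev: float, epoch: int, config: OptimizerConfig
) -> float:
    """Adaptive momentum from the two most recent losses.

    Returns ``default_momentum`` for epochs 0 and 1; afterwards
    min(beta / (1 - exp(-(loss_t + loss_prev))), momentum_cap).  A zero
    loss sum makes the formula diverge, so the cap is returned directly
    (continuity from below).
    """
    for name, loss in (("loss_t", loss_t), ("loss_prev", loss_prev)):
        if not math.isfinite(loss) or loss < 0.0:
            raise ValueError(f"{name} must be finite and >= 0, got {loss!r}")
    if epoch < 2:
        return config.default_momentum
    s = loss_t + loss_prev
    if s == 0.0:
        return config.momentum_cap
    raw = config.beta / (1.0 - math.exp(-s))
    return min(raw, config.momentum_cap)


def lr_schedule(epoch: int, config: OptimizerConfig) -> float:
    """lr(epoch) = initial_lr * lr_decay**epoch; strictly decreasing."""
    if epoch < 0:
        raise ValueError(f"epoch must be non-negative, got {epoch}")
    return config.initial_lr * config.lr_decay ** epoch


def sgd_step(
    weights: np.ndarray,
    gradients: np.ndarray,
    state: OptimizerState,
    config: OptimizerConfig,
) -> tuple[np.ndarray, OptimizerState]:
    """One heavy-ball descent step on a parameter array.

    velocity <- current_momentum * velocity - current_lr * gradient
    weights  <- weights + velocity
    """
    weights = np.asarray(weights, dtype=float)
    gradients = np.asarray(gradients, dtype=float)
    if weights.shape != gradients.shape:
        raise ValueError(
            f"weights shape {weights.shape} != gradients shape {gradients.shape}"
        )
    if state.velocity is None:
        state.velocity = np.zeros_like(weights)
    elif state.velocity.shape != weights.shape:
        raise ValueError(
            f"velocity shape {state.velocity.shape} != weights shape {weights.shape}"
        )
    state.velocity = (
        state.current_momentum * state.velocity - state.current_lr * gradients
    )
    return weights + state.velocity, state


def bias_step(
    bias: np.ndarray,
    layer_inputs: np.ndarray,
    layer_weights: np.ndarray,
    activation_value: float,
    error_signal: float,
    state: OptimizerState,
    config: OptimizerConfig,
) -> np.ndarray:
    """Sigmoid-style bias update: b <- b + lr * f(H)(1 - f(H)) * x * w * e."""
    if not 0.0 < activation_value < 1.0:
        raise ValueError("activation_value must lie in (0, 1)")
    bias = np.asarray(bias, dtype=float)
    increment = (
        state.current_lr
        * activation_value
        * (1.0 - activation_value)
        * np.asarray(layer_inputs, dtype=float)
        * np.asarray(layer_weights, dtype=float)
        * error_signal
    )
    return bias + increment


def epoch_hook(
    state: OptimizerState, epoch_loss: float, config: OptimizerConfig
) -> OptimizerState:
    """Record the epoch's evaluation loss and refresh the schedule.

    The learning rate depends only on the epoch index; the momentum uses
    the two most recent recorded losses.
    """
    state.loss_history.append(float(epoch_loss))
    state.epoch += 1
    state.current_lr = lr_schedule(state.epoch, config)
    if len(state.loss_history) >= 2:
        loss_t, loss_prev = state.loss_history[-1], state.loss_history[-2]
    else:
        loss_t = loss_prev = state.loss_history[-1]
    state.current_momentum = calculate_momentum(
        loss_t, loss_prev, state.epoch, config
    )
    return state


# ---------------------------------------------------------------------------
# optimizer objects used by the training loop
# ---------------------------------------------------------------------------

class AdaptiveSGD:
    """Coordinates the adaptive schedule across many parameter arrays.

    ``step`` applies one heavy-ball update per parameter tensor;
    ``end_epoch`` feeds the epoch's evaluation loss back into the
    schedule so the next epoch's learning rate and momentum adapt.
    """

    name = "adaptive_sgd"

    def __init__(self, config: OptimizerConfig | None = None):
        self.config = config or OptimizerConfig()
        self.epoch = 0
        self.loss_history: list[float] = []
        self.current_lr = lr_schedule(0, self.config)
        self.current_momentum = self.config.default_momentum
        self._velocities: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for i, (p, g) in enumerate(zip(params, grads)):
            v = self._velocities.get(i)
            if v is None:
                v = np.zeros_like(p)
            v = self.current_momentum * v - self.current_lr * g
            p += v
            self._velocities[i] = v

    def end_epoch(self, eval_loss: float) -> None:
        self.loss_history.append(float(eval_loss))
        self.epoch += 1
        self.current_lr = lr_schedule(self.epoch, self.config)
        if len(self.loss_history) >= 2:
            loss_t, loss_prev = self.loss_history[-1], self.loss_history[-2]
        else:
            loss_t = loss_prev = self.loss_history[-1]
        self.current_momentum = calculate_momentum(
            loss_t, loss_prev, self.epoch, self.config
        )


class MomentumSGD:
    """Fixed learning rate, fixed momentum — the non-adaptive baseline."""

    name = "sgd"

    def __init__(self, lr: float = 0.01, momentum: float = 0.9):
        self.current_lr = lr
        self.current_momentum = momentum
        self._velocities: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for i, (p, g) in enumerate(zip(params, grads)):
            v = self._velocities.get(i)
            if v is None:
                v = np.zeros_like(p)
            v = self.current_momentum * v - self.current_lr * g
            p += v
            self._velocities[i] = v

    def end_epoch(self, eval_loss: float) -> None:
        pass


class Adam:
    """Thin Adam baseline for comparison runs."""

    name = "adam"

    def __init__(self, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.current_lr = lr
        self.current_momentum = beta1
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self._t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            m = self._m.get(i, np.zeros_like(p))
            v = self._v.get(i, np.zeros_like(p))
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1 ** self._t)
            v_hat = v / (1 - self.beta2 ** self._t)
            p -= self.current_lr * m_hat / (np.sqrt(v_hat) + self.eps)
            self._m[i], self._v[i] = m, v

    def end_epoch(self, eval_loss: float) -> None:
        pass


def write_training_log(path, records: list[dict]) -> None:
    """Append-style CSV log of (epoch, lr, momentum, loss) rows."""
    path = Path(path)
    fieldnames = ["epoch", "lr", "momentum", "loss"]
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=fieldnames)
        writer.writeheader()
        for rec in records:
            writer.writerow({k: rec[k] for k in fieldnames})
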