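"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "CosineAnnealingLR"]


class Adam:
    def __init__(self, params, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    # -- checkpoint support ------------------------------------------------
    def state_dict(self) -> dict:
        state = {"t": np.asarray(self.t), "lr": np.asarray(self.lr)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            state[f"m.{i}"] = m.copy()
            state[f"v.{i}"] = v.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        self.m = [state[f"m.{i}"].copy() for i in range(len(self.params))]
        self.v = [state[f"v.{i}"].copy() for i in range(len(self.params))]


class CosineAnnealingLR:
    """Anneals the optimizer lr from its base value to ``eta_min`` over
    ``t_max`` steps following a half cosine."""

    def __init__(self, optimizer: Adam, t_max: int, eta_min: float = 1e-5):
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.t_max = max(t_max, 1)
        self.eta_min = eta_min
        self.t = 0

    def step(self) -> float:
        self.t = min(self.t + 1, self.t_max)
        lr = self.eta_min + 0.5 * (self.base_lr - self.eta_min) * (
            1 + math.cos(math.pi * self.t / self.t_max))
        self.optimizer.lr = lr
        return lr

    @property
    def lr(self) -> float:
        return self.optimizer.lr
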