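"""Optimizers for the NumPy layer stack."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .layers import Sequential


class Optimizer:
    def __init__(self, model: Sequential, lr: float) -> None:
        self.model = model
        self.lr = lr
        self.state: dict = {}

    def zero_grad(self) -> None:
        self.model.zero_grad()

    def step(self) -> None:
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, model: Sequential, lr: float, betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        super().__init__(model, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for name, p, g in self.model.named_params():
            m, v = self.state.setdefault(name, (np.zeros_like(p), np.zeros_like(p)))
            m = self.b1 * m + (1 - self.b1) * g
            v = self.b2 * v + (1 - self.b2) * g * g
            self.state[name] = (m, v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, model: Sequential, lr: float, alpha: float = 0.99, eps: float = 1e-8) -> None:
        super().__init__(model, lr)
        self.alpha = alpha
        self.eps = eps

    def step(self) -> None:
        for name, p, g in self.model.named_params():
            sq = self.state.setdefault(name, np.zeros_like(p))
            sq = self.alpha * sq + (1 - self.alpha) * g * g
            self.state[name] = sq
            p -= self.lr * g / (np.sqrt(sq) + self.eps)
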