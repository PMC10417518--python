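"""Optimisers. Only stochastic gradient descent with classical momentum
is provided — the training schedule used throughout the package."""

from __future__ import annotations

from typing import Iterable, List

import numpy as np

from .tensor import Tensor

__all__ = ["SGD"]


class SGD:
    """SGD with momentum: v ← m·v + g; p ← p − lr·v."""

    def __init__(self, params: Iterable[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params: List[Tensor] = list(params)
        if not self.params:
            raise ValueError("SGD received no parameters")
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
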