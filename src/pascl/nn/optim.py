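"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["SGD"]


class SGD:
    """v <- momentum * v + g;  p <- p - lr * v.

    ``clip_norm`` rescales the whole gradient when its global L2 norm
    exceeds the bound — a standard guard for spiky loss surfaces.
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0,
                 clip_norm: float | None = None):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad**2).sum()) for p in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    p.grad *= scale
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v += p.grad
            p.value -= self.lr * v
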