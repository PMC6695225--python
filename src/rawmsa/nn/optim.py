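"""Optimizers for the numpy network stack."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["RMSprop"]


class RMSprop:
    """RMSprop with exponentially decaying squared-gradient cache.

    Defaults follow the common convention for this optimizer family:
    learning rate 1e-3, decay 0.9, epsilon 1e-7.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        rho: float = 0.9,
        eps: float = 1e-7,
        clip_norm: float | None = None,
    ):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.clip_norm = clip_norm
        self.cache = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
            )
            scale = self.clip_norm / (total + 1e-12) if total > self.clip_norm else 1.0
        else:
            scale = 1.0
        for p, c in zip(self.params, self.cache):
            if p.grad is None:
                continue
            g = p.grad * scale
            c *= self.rho
            c += (1.0 - self.rho) * g**2
            p.data -= self.lr * g / (np.sqrt(c) + self.eps)
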