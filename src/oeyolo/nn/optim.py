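"""Optimization: SGD with momentum and decoupled-from-loss L2 weight decay,
plus the cosine-annealing learning-rate schedule used for detector training.
"""

from __future__ import annotations

import math
from typing import List, Sequence

import numpy as np

from oeyolo.nn.tensor import Tensor

__all__ = ["SGD", "cosine_lr"]


class SGD:
    """Stochastic gradient descent with classical momentum.

    Weight decay adds ``wd * p`` to the gradient (L2 regularization) for every
    parameter flagged ``decay=True`` at construction (by default all).
    """

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 0.01,
        momentum: float = 0.937,
        weight_decay: float = 0.0,
    ):
        self.params: List[Tensor] = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

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

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(initial_lr: float, epoch: int, total_epochs: int, min_lr: float | None = None) -> float:
    """Cosine annealing: lr(0) = initial_lr, lr(total_epochs - 1) = min_lr.

    ``min_lr`` defaults to ``initial_lr / 100``.
    """
    if min_lr is None:
        min_lr = initial_lr / 100.0
    if total_epochs <= 1:
        return initial_lr
    t = epoch / (total_epochs - 1)
    return min_lr + 0.5 * (initial_lr - min_lr) * (1.0 + math.cos(math.pi * t))
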