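"""Adam optimizer and the cosine-annealing learning-rate schedule."""
from __future__ import annotations

import math

import numpy as np


def cosine_annealing_lr(epoch: int, lr_max: float, lr_min: float,
                        period: int = 5, restart_decay: float = 1.0) -> float:
    """Learning rate for ``epoch`` under cosine annealing with warm restarts.

    Within each ``period``-epoch cycle the rate decays from ``lr_max`` to
    ``lr_min`` along a half cosine, then restarts:
    ``lr = lr_min + (lr_max - lr_min) * (1 + cos(pi * t / period)) / 2``
    with ``t = epoch mod period``.  ``restart_decay`` scales the peak of
    each successive cycle (1.0 reproduces plain warm restarts; < 1 keeps
    late restarts from throwing away a converged state).
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    cycle, t = divmod(epoch, period)
    peak = lr_min + (lr_max - lr_min) * restart_decay ** cycle
    return lr_min + (peak - lr_min) * (1.0 + math.cos(math.pi * t / period)) / 2.0


class Adam:
    """Adam over a parameter list of ``(owner, attr, grad_attr)`` triples."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, a)) for o, a, _ in self.params]
        self.v = [np.zeros_like(getattr(o, a)) for o, a, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (obj, attr, gattr) in enumerate(self.params):
            g = getattr(obj, gattr)
            m, v = self.m[i], self.v[i]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            update = (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps))
            setattr(obj, attr, getattr(obj, attr) - update.astype(np.float32))
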