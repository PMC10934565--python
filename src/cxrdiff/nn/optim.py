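"""Adam optimizer and plateau learning-rate scheduler."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply lr by ``factor`` after ``patience`` consecutive
    non-improving evaluations (lower metric value = better)."""

    def __init__(self, optimizer: Adam, factor: float = 0.1,
                 patience: int = 3, min_delta: float = 0.0):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_count = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, metric: float) -> bool:
        """Record one evaluation; returns True if the lr was reduced."""
        if metric < self.best - self.min_delta:
            self.best = metric
            self.bad_count = 0
            return False
        self.bad_count += 1
        if self.bad_count >= self.patience:
            self.optimizer.lr *= self.factor
            self.bad_count = 0
            return True
        return False
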