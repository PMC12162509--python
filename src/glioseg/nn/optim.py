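"""Optimizers and learning-rate schedules for network training."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Adam:
    """Adam with decoupled L2 weight decay added to the gradient.

    Matches the conventional formulation: first/second moment estimates with
    bias correction; ``weight_decay`` contributes ``wd * theta`` to the
    gradient (L2 regularization, not AdamW decoupling).
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer's lr when a metric stops improving."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-6, min_delta: float = 1e-6):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.min_delta = min_delta
        self.best = np.inf
        self.num_bad = 0

    def step(self, metric: float):
        if metric < self.best - self.min_delta:
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.num_bad = 0


class EarlyStopper:
    """Signal a stop after ``patience`` consecutive non-improving epochs."""

    def __init__(self, patience: int = 10, min_delta: float = 1e-6):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.num_bad = 0

    def update(self, metric: float) -> bool:
        """Record a validation metric; return True when training should stop."""
        if metric < self.best - self.min_delta:
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
        return self.num_bad >= self.patience
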