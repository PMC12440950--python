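"""SGD with momentum, weight decay, warmup and cosine decay."""

from __future__ import annotations

import math
from typing import List, Optional

import numpy as np

from .autograd import Parameter


class SGD:
    """Momentum SGD matching the common single-stage-detector recipe.

    Defaults: momentum 0.937, weight decay 5e-4; weight decay is skipped
    for 1-d parameters (norm scales/shifts, biases).
    """

    def __init__(
        self,
        params: List[Parameter],
        lr: float = 0.01,
        momentum: float = 0.937,
        weight_decay: float = 5e-4,
    ):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class WarmupCosineSchedule:
    """Linear warmup to `lr_max`, then cosine decay to `lr_final`."""

    def __init__(self, optimizer: SGD, lr_max: float, total_steps: int,
                 warmup_steps: int = 0, lr_final: Optional[float] = None):
        self.opt = optimizer
        self.lr_max = lr_max
        self.total = max(total_steps, 1)
        self.warmup = warmup_steps
        self.lr_final = lr_max * 0.01 if lr_final is None else lr_final
        self.t = 0

    def step(self) -> float:
        self.t += 1
        if self.warmup and self.t <= self.warmup:
            lr = self.lr_max * self.t / self.warmup
        else:
            frac = (self.t - self.warmup) / max(self.total - self.warmup, 1)
            frac = min(frac, 1.0)
            lr = self.lr_final + 0.5 * (self.lr_max - self.lr_final) * (1 + math.cos(math.pi * frac))
        self.opt.lr = lr
        return lr
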