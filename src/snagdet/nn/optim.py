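"""AdamW optimizer with decoupled weight decay and linear LR decay."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["AdamW", "linear_decay"]


class AdamW:
    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grad_clip: float | None = None) -> None:
        self.t += 1
        if grad_clip is not None:
            total = np.sqrt(sum(float((p.grad**2).sum())
                                for p in self.params if p.grad is not None))
            scale = grad_clip / max(total, grad_clip)
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def linear_decay(lr0: float, step: int, total_steps: int, floor: float = 0.0) -> float:
    """Linearly decay from ``lr0`` to ``floor`` over ``total_steps``."""
    frac = min(step / max(total_steps, 1), 1.0)
    return lr0 + (floor - lr0) * frac
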