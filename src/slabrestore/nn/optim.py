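"""ADAM optimizer and cosine learning-rate decay."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "cosine_lr"]


def cosine_lr(step: int, total_steps: int, lr_max: float = 1e-4, lr_min: float = 1e-8) -> float:
    """Cosine decay from ``lr_max`` (step 0) to ``lr_min`` (final step)."""
    if total_steps <= 1:
        return lr_max
    t = min(max(step, 0), total_steps - 1) / (total_steps - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + np.cos(np.pi * t))


class Adam:
    """Standard ADAM with bias correction (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
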