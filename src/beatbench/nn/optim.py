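"""Optimizers (Adam) and weight clipping."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "clip_parameters"]


class Adam:
    """Adam with the adversarial-training defaults (lr 2e-4, beta1 0.5)."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clip_parameters(params: list[Tensor], clip_value: float) -> None:
    """In-place clamp of every parameter to [-clip_value, clip_value]
    (Wasserstein critic Lipschitz constraint)."""
    for p in params:
        np.clip(p.data, -clip_value, clip_value, out=p.data)
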