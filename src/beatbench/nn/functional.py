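"""Loss functions composed from autograd primitives."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["bce_loss", "l1_loss", "mse_loss", "kl_gaussian", "cross_entropy_logits"]

_EPS = 1e-12


def bce_loss(prob: Tensor, target: "Tensor | np.ndarray | float") -> Tensor:
    """Binary cross-entropy on probabilities (post-sigmoid)."""
    t = target if isinstance(target, Tensor) else Tensor(np.broadcast_to(np.asarray(target, dtype=float), prob.shape).copy())
    return -((t * (prob + _EPS).log() + (1.0 - t) * (1.0 - prob + _EPS).log()).mean())


def l1_loss(x: Tensor, y: "Tensor | np.ndarray") -> Tensor:
    y = y if isinstance(y, Tensor) else Tensor(y)
    return (x - y).abs().mean()


def mse_loss(x: Tensor, y: "Tensor | np.ndarray") -> Tensor:
    y = y if isinstance(y, Tensor) else Tensor(y)
    return ((x - y) ** 2.0).mean()


def kl_gaussian(mu: Tensor, logvar: Tensor) -> Tensor:
    """KL( N(mu, exp(logvar)) || N(0, 1) ), mean over the batch."""
    per_sample = (-0.5 * (1.0 + logvar - mu**2.0 - logvar.exp())).sum(axis=1)
    return per_sample.mean()


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Softmax cross-entropy from raw logits and integer labels."""
    n, k = logits.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant: gradient-free shift
    z = logits - shift
    log_norm = z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros((n, k))
    onehot[np.arange(n), np.asarray(labels, dtype=int)] = 1.0
    picked = (z * Tensor(onehot)).sum(axis=1, keepdims=True)
    return (log_norm - picked).mean()
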