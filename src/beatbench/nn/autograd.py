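"""Reverse-mode automatic differentiation on numpy arrays.

A minimal dynamic tape: each ``Tensor`` wraps a float64 ndarray and
remembers how to push its output gradient to its parents.  ``backward()``
on a scalar walks the tape in reverse topological order.  Broadcasting in
forward ops is undone in the backward pass by summing over broadcast axes.

Only the operations the generative models and the 1-D residual classifier
need are implemented: elementwise arithmetic, matmul, activations,
reductions, reshape/concat/slicing, and 1-D (transposed) convolution via
im2col.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "conv_transpose1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers ---------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1.0),)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            return (g @ other.data.T, self.data.T @ g)

        out._backward = bwd
        return out

    # -- nonlinearities ----------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * (1.0 - y * y),)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * y * (1.0 - y),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * factor, parents=(self,))
        out._backward = lambda g: (g * factor,)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * y,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def abs(self):
        s = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: (g * s,)
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g2 = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    g2 = np.expand_dims(g2, ax)
            return (np.broadcast_to(g2, self.data.shape).copy(),)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        out._backward = bwd
        return out

    # -- autodiff driver ---------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g, dtype=np.float64, copy=True)
                else:
                    parent.grad += g

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# 1-D convolution (im2col) and its transpose
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(B, C, L) -> (B, C, L_out, K) view of sliding windows."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    B, C, L = x.shape
    L_out = (L - k) // stride + 1
    s0, s1, s2 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, shape=(B, C, L_out, k), strides=(s0, s1, s2 * stride, s2), writeable=False
    )
    return np.ascontiguousarray(cols)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (B, C_in, L); w: (C_out, C_in, K); b: (C_out,) -> (B, C_out, L_out)."""
    B, C, L = x.data.shape
    C_out, _, K = w.data.shape
    L_out = (L + 2 * pad - K) // stride + 1
    if L_out < 1:
        raise ValueError(f"conv1d output length {L_out} < 1 (L={L}, K={K}, stride={stride}, pad={pad})")
    cols = _im2col(x.data, K, stride, pad)  # (B, C, L_out, K)
    out_data = np.einsum("bclk,ock->bol", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def bwd(g):
        dw = np.einsum("bol,bclk->ock", g, cols, optimize=True)
        dx_pad = np.zeros((B, C, L + 2 * pad))
        for kk in range(K):
            # dx_pad[:, :, kk + stride*l] += sum_o g[:, o, l] * w[o, :, kk]
            contrib = np.einsum("bol,oc->bcl", g, w.data[:, :, kk], optimize=True)
            dx_pad[:, :, kk : kk + stride * L_out : stride] += contrib
        dx = dx_pad[:, :, pad : pad + L] if pad else dx_pad
        if b is None:
            return (dx, dw)
        return (dx, dw, g.sum(axis=(0, 2)))

    out._backward = bwd
    return out


def conv_transpose1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2, pad: int = 1) -> Tensor:
    """x: (B, C_in, L); w: (C_in, C_out, K) -> (B, C_out, (L-1)*stride - 2*pad + K)."""
    B, C_in, L = x.data.shape
    _, C_out, K = w.data.shape
    L_full = (L - 1) * stride + K
    L_out = L_full - 2 * pad
    if L_out < 1:
        raise ValueError("conv_transpose1d output length < 1")
    full = np.zeros((B, C_out, L_full))
    for kk in range(K):
        contrib = np.einsum("bcl,co->bol", x.data, w.data[:, :, kk], optimize=True)
        full[:, :, kk : kk + stride * L : stride] += contrib
    out_data = full[:, :, pad : pad + L_out] if pad else full
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def bwd(g):
        g_full = np.zeros((B, C_out, L_full))
        g_full[:, :, pad : pad + L_out] = g
        dx = np.zeros((B, C_in, L))
        dw = np.zeros_like(w.data)
        for kk in range(K):
            sl = g_full[:, :, kk : kk + stride * L : stride]  # (B, C_out, L)
            dx += np.einsum("bol,co->bcl", sl, w.data[:, :, kk], optimize=True)
            dw[:, :, kk] = np.einsum("bcl,bol->co", x.data, sl, optimize=True)
        if b is None:
            return (dx, dw)
        return (dx, dw, g.sum(axis=(0, 2)))

    out._backward = bwd
    return out
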