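"""Neural-network layers on top of the autograd tape.

Initialization convention (applied through a caller-supplied numpy
``Generator`` so builds are reproducible): affine/conv weights drawn from
N(0, 0.02), biases zero, batch-norm scale from N(1, 0.02) with zero shift
— the DCGAN-era recipe.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv1d, conv_transpose1d

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "ConvTranspose1d",
    "BatchNorm1d",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Flatten",
    "GlobalAvgPool1d",
    "Sequential",
    "BiLSTM",
    "INIT_SD",
]

INIT_SD = 0.02


class Module:
    """Base class: parameter discovery, train/eval mode, call protocol."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, flag: bool = True) -> "Module":
        for m in self.modules():
            m.training = flag
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameter arrays plus running stats, in order."""
        arrs = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                arrs += [m.running_mean, m.running_var]
        return arrs

    def load_state_arrays(self, arrs: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrs):
            raise ValueError("state array count mismatch")
        for dst, src in zip(own, arrs):
            if dst.shape != np.asarray(src).shape:
                raise ValueError("state array shape mismatch")
            dst[...] = src

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.in_features, self.out_features = in_features, out_features
        self.weight = Tensor(rng.normal(0.0, INIT_SD, (in_features, out_features)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0):
        self.stride, self.pad = stride, pad
        self.weight = Tensor(rng.normal(0.0, INIT_SD, (out_ch, in_ch, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 2, pad: int = 1):
        self.stride, self.pad = stride, pad
        self.weight = Tensor(rng.normal(0.0, INIT_SD, (in_ch, out_ch, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose1d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm1d(Module):
    """Batch normalization over (B,) or (B, L) slices per feature/channel.

    Accepts (B, F) or (B, C, L) inputs.  Training mode normalizes with
    batch statistics and updates exponential running estimates; eval mode
    uses the running estimates.
    """

    def __init__(self, num_features: int, rng: np.random.Generator,
                 momentum: float = 0.1, eps: float = 1e-5):
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(rng.normal(1.0, INIT_SD, num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) if x.data.ndim == 2 else (0, 2)
        shape = (1, -1) if x.data.ndim == 2 else (1, -1, 1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.data.shape[0], -1)


class GlobalAvgPool1d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=2)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class _LSTMCell(Module):
    """One LSTM step from zero state (the generators feed a single time step)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.hidden_size = hidden_size
        self.w_ih = Tensor(rng.normal(0.0, INIT_SD, (input_size, 4 * hidden_size)), requires_grad=True)
        self.w_hh = Tensor(rng.normal(0.0, INIT_SD, (hidden_size, 4 * hidden_size)), requires_grad=True)
        self.bias = Tensor(np.zeros(4 * hidden_size), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        # zero initial state: the w_hh contribution vanishes but stays a
        # (trainable) parameter of the cell for architectural fidelity
        h = self.hidden_size
        gates = x @ self.w_ih + self.bias
        i = gates[:, 0:h].sigmoid()
        f = gates[:, h : 2 * h].sigmoid()  # noqa: F841 - gate exists, zero cell state
        g = gates[:, 2 * h : 3 * h].tanh()
        o = gates[:, 3 * h : 4 * h].sigmoid()
        c = i * g
        return o * c.tanh()


class BiLSTM(Module):
    """Stacked bidirectional LSTM applied to a single time step.

    With one time step both directions see the same input; each direction
    has its own weights and the layer output is the concatenation of the
    two hidden states (2 * hidden_size features).
    """

    def __init__(self, input_size: int, hidden_size: int, num_layers: int, rng: np.random.Generator):
        self.cells_fwd = []
        self.cells_bwd = []
        size = input_size
        for _ in range(num_layers):
            self.cells_fwd.append(_LSTMCell(size, hidden_size, rng))
            self.cells_bwd.append(_LSTMCell(size, hidden_size, rng))
            size = 2 * hidden_size

    def forward(self, x: Tensor) -> Tensor:
        for fwd, bwd in zip(self.cells_fwd, self.cells_bwd):
            x = concat([fwd(x), bwd(x)], axis=1)
        return x
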