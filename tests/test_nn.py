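"""Autodiff engine: numerical gradient checks and optimizer behaviour.

Every composite layer the models rely on (conv, transposed conv,
batch-norm, the single-step bidirectional LSTM, the loss heads) is checked
against central finite differences.
"""

import numpy as np
import pytest

from beatbench import nn
from beatbench.nn.autograd import Tensor, concat, conv1d, conv_transpose1d


def numerical_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def test_elementwise_and_broadcast_gradients(rng):
    a = Tensor(rng.standard_normal((3, 4)), requires_grad=True)
    b = Tensor(rng.standard_normal(4), requires_grad=True)

    def f():
        return float((((Tensor(a.data) * Tensor(b.data) + Tensor(b.data)).tanh() ** 2.0).mean()).data)

    loss = ((a * b + b).tanh() ** 2.0).mean()
    loss.backward()
    np.testing.assert_allclose(a.grad, numerical_grad(f, a.data), atol=1e-8)
    np.testing.assert_allclose(b.grad, numerical_grad(f, b.data), atol=1e-8)


def test_matmul_slice_concat_gradients(rng):
    w = Tensor(rng.standard_normal((5, 4)), requires_grad=True)
    x = rng.standard_normal((2, 5))

    def f():
        h = Tensor(x) @ Tensor(w.data)
        out = concat([h[:, 0:2], h[:, 2:4]], axis=1)
        return float((out.sigmoid().sum()).data)

    h = Tensor(x) @ w
    loss = concat([h[:, 0:2], h[:, 2:4]], axis=1).sigmoid().sum()
    loss.backward()
    np.testing.assert_allclose(w.grad, numerical_grad(f, w.data), atol=1e-8)


@pytest.mark.parametrize("stride,pad", [(1, 0), (2, 1)])
def test_conv1d_gradients(rng, stride, pad):
    x = Tensor(rng.standard_normal((2, 3, 10)), requires_grad=True)
    w = Tensor(0.1 * rng.standard_normal((4, 3, 4)), requires_grad=True)
    b = Tensor(0.1 * rng.standard_normal(4), requires_grad=True)

    def f():
        return float((conv1d(Tensor(x.data), Tensor(w.data), Tensor(b.data), stride, pad) ** 2.0).sum().data)

    (conv1d(x, w, b, stride, pad) ** 2.0).sum().backward()
    for t in (x, w, b):
        np.testing.assert_allclose(t.grad, numerical_grad(f, t.data), atol=1e-7)


def test_conv_transpose1d_gradients(rng):
    x = Tensor(rng.standard_normal((2, 3, 5)), requires_grad=True)
    w = Tensor(0.1 * rng.standard_normal((3, 4, 4)), requires_grad=True)
    b = Tensor(0.1 * rng.standard_normal(4), requires_grad=True)

    def f():
        return float((conv_transpose1d(Tensor(x.data), Tensor(w.data), Tensor(b.data), 2, 1).tanh()).sum().data)

    conv_transpose1d(x, w, b, 2, 1).tanh().sum().backward()
    for t in (x, w, b):
        np.testing.assert_allclose(t.grad, numerical_grad(f, t.data), atol=1e-7)


def test_conv_transpose_output_length(rng):
    x = Tensor(rng.standard_normal((1, 2, 8)))
    w = Tensor(rng.standard_normal((2, 3, 4)))
    assert conv_transpose1d(x, w, None, 2, 1).shape == (1, 3, 16)
    assert conv_transpose1d(x, w, None, 4, 0).shape == (1, 3, 32)


def test_batchnorm_and_cross_entropy_gradients(rng):
    lin = nn.Linear(6, 3, rng)
    bn = nn.BatchNorm1d(3, rng)
    x = rng.standard_normal((5, 6))
    y = np.array([0, 1, 2, 1, 0])

    def f():
        return float(nn.cross_entropy_logits(bn(lin(Tensor(x))), y).data)

    nn.cross_entropy_logits(bn(lin(Tensor(x))), y).backward()
    for t in (lin.weight, lin.bias, bn.gamma, bn.beta):
        np.testing.assert_allclose(t.grad, numerical_grad(f, t.data), atol=1e-7)


def test_batchnorm_eval_mode_uses_running_stats(rng):
    bn = nn.BatchNorm1d(3, rng)
    x = rng.standard_normal((64, 3)) * 2.0 + 5.0
    for _ in range(200):
        bn(Tensor(x))
    bn.eval()
    out = bn(Tensor(x)).data
    expected = (x - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
    expected = expected * bn.gamma.data + bn.beta.data
    np.testing.assert_allclose(out, expected, atol=1e-9)


def test_bilstm_gradients(rng):
    lstm = nn.BiLSTM(4, 5, 2, rng)
    x = rng.standard_normal((3, 4))

    def f():
        return float(((lstm(Tensor(x)) ** 2.0).sum()).data)

    (lstm(Tensor(x)) ** 2.0).sum().backward()
    cell = lstm.cells_fwd[0]
    np.testing.assert_allclose(cell.w_ih.grad, numerical_grad(f, cell.w_ih.data), atol=1e-7)
    assert lstm(Tensor(x)).shape == (3, 10)


def test_bce_matches_closed_form():
    p = Tensor(np.array([0.2, 0.8, 0.5]))
    got = nn.bce_loss(p, np.array([0.0, 1.0, 0.0])).item()
    manual = -np.mean([np.log(1 - 0.2), np.log(0.8), np.log(1 - 0.5)])
    assert got == pytest.approx(manual, abs=1e-9)


def test_kl_gaussian_zero_at_standard_normal():
    mu = Tensor(np.zeros((4, 3)), requires_grad=True)
    logvar = Tensor(np.zeros((4, 3)), requires_grad=True)
    assert nn.kl_gaussian(mu, logvar).item() == pytest.approx(0.0, abs=1e-12)
    # positive away from the prior
    assert nn.kl_gaussian(Tensor(np.ones((2, 2))), Tensor(np.zeros((2, 2)))).item() > 0


def test_adam_reduces_quadratic():
    target = np.array([1.0, -2.0, 3.0])
    p = Tensor(np.zeros(3), requires_grad=True)
    opt = nn.Adam([p], lr=0.1)
    for _ in range(200):
        loss = ((p - Tensor(target)) ** 2.0).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    np.testing.assert_allclose(p.data, target, atol=1e-2)


def test_clip_parameters_bounds_in_place(rng):
    p = Tensor(rng.standard_normal(100), requires_grad=True)
    nn.clip_parameters([p], 0.01)
    assert np.all(np.abs(p.data) <= 0.01)
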