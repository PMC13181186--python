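"""Checks of the autodiff core against independent numerical oracles."""

import numpy as np
import pytest
from scipy import signal

from mbleformer import nn
from mbleformer.nn import Tensor


def numerical_grad(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar f w.r.t. x (float64 staging)."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f(x)
        flat[i] = orig - eps
        lo = f(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


def check_grad(op, shape, seed=0, atol=2e-2, rtol=5e-2):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0, 1, shape).astype(np.float32)

    def scalar(x):
        t = Tensor(x)
        return float((op(t) ** 2).sum().data)

    t = Tensor(x0.copy(), requires_grad=True)
    y = (op(t) ** 2).sum()
    y.backward()
    num = numerical_grad(scalar, x0.copy())
    assert np.allclose(t.grad, num, atol=atol, rtol=rtol)


@pytest.mark.parametrize("name,op,shape", [
    ("sigmoid", nn.sigmoid, (3, 4)),
    ("relu", nn.relu, (3, 4)),
    ("softmax", lambda t: nn.softmax(t, axis=-1), (2, 5)),
    ("mean_axis", lambda t: t.mean(axis=1, keepdims=True), (3, 4)),
    ("reshape_t", lambda t: t.reshape(4, 3).transpose(1, 0), (3, 4)),
    ("slice", lambda t: t[:, 1:3], (3, 4)),
    ("roll", lambda t: t.roll((1, -1)), (2, 2, 3, 3)),
    ("pad", lambda t: t.pad2d(1, 1, 0, 2), (2, 2, 3, 3)),
    ("upsample", lambda t: nn.bilinear_upsample(t, 2), (1, 2, 3, 3)),
    ("clip", lambda t: t.clip(-0.5, 0.5), (3, 4)),
])
def test_op_gradients_match_finite_differences(name, op, shape):
    check_grad(op, shape)


def test_matmul_gradient():
    rng = np.random.default_rng(1)
    a0 = rng.normal(0, 1, (3, 4)).astype(np.float32)
    b0 = rng.normal(0, 1, (4, 2)).astype(np.float32)
    a = Tensor(a0.copy(), requires_grad=True)
    b = Tensor(b0.copy(), requires_grad=True)
    ((a @ b) ** 2).sum().backward()
    num_a = numerical_grad(lambda x: float(((Tensor(x) @ Tensor(b0)) ** 2).sum().data),
                           a0.copy())
    num_b = numerical_grad(lambda x: float(((Tensor(a0) @ Tensor(x)) ** 2).sum().data),
                           b0.copy())
    assert np.allclose(a.grad, num_a, atol=2e-2, rtol=5e-2)
    assert np.allclose(b.grad, num_b, atol=2e-2, rtol=5e-2)


def test_fancy_index_gradient_accumulates_repeats():
    t = Tensor(np.array([1.0, 2.0, 3.0], dtype=np.float32), requires_grad=True)
    idx = np.array([0, 0, 2])
    t[idx].sum().backward()
    assert np.array_equal(t.grad, [2.0, 0.0, 1.0])


@pytest.mark.parametrize("dilation", [1, 2])
def test_conv2d_forward_matches_scipy(dilation):
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, (1, 2, 8, 8)).astype(np.float32)
    conv = nn.Conv2d(2, 3, 3, rng, dilation=dilation)
    out = conv(Tensor(x)).data
    # oracle: per-channel correlation with zero padding
    k = conv.weight.data
    pad = dilation
    kd = np.zeros((3, 2, 2 * dilation + 1, 2 * dilation + 1))
    kd[:, :, ::dilation, ::dilation] = k     # insert dilation holes
    for co in range(3):
        acc = np.zeros((8, 8))
        for ci in range(2):
            acc += signal.correlate2d(x[0, ci], kd[co, ci], mode="same")
        acc += conv.bias.data[co]
        assert np.allclose(out[0, co], acc, atol=1e-5)


def test_conv2d_gradients():
    rng = np.random.default_rng(4)
    x0 = rng.normal(0, 1, (2, 2, 5, 5)).astype(np.float32)
    conv = nn.Conv2d(2, 2, 3, rng)
    w0 = conv.weight.data.copy()

    x = Tensor(x0.copy(), requires_grad=True)
    (conv(x) ** 2).sum().backward()

    num_x = numerical_grad(
        lambda a: float((conv(Tensor(a)) ** 2).sum().data), x0.copy())
    assert np.allclose(x.grad, num_x, atol=2e-2, rtol=5e-2)

    def loss_w(w):
        conv.weight.data = w.astype(np.float32)
        return float((conv(Tensor(x0)) ** 2).sum().data)

    num_w = numerical_grad(loss_w, w0.copy())
    conv.weight.data = w0
    assert np.allclose(conv.weight.grad, num_w, atol=2e-2, rtol=5e-2)


def test_bilinear_upsample_preserves_constants():
    x = Tensor(np.full((1, 1, 3, 5), 3.25, dtype=np.float32))
    up = nn.bilinear_upsample(x, 2)
    assert up.shape == (1, 1, 6, 10)
    assert np.allclose(up.data, 3.25)


def test_layernorm_normalises_last_axis():
    rng = np.random.default_rng(5)
    ln = nn.LayerNorm(8)
    x = Tensor(rng.normal(3, 2, (4, 8)).astype(np.float32))
    y = ln(x).data
    assert np.allclose(y.mean(axis=-1), 0, atol=1e-5)
    assert np.allclose(y.std(axis=-1), 1, atol=1e-2)


def test_batchnorm_train_eval_consistency():
    rng = np.random.default_rng(6)
    bn = nn.BatchNorm2d(3)
    x = rng.normal(2, 3, (4, 3, 5, 5)).astype(np.float32)
    for _ in range(50):   # converge running stats on a fixed batch
        bn(Tensor(x))
    bn.eval()
    y = bn(Tensor(x)).data
    assert np.allclose(y.mean(axis=(0, 2, 3)), 0, atol=5e-2)


def test_adam_minimises_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0], dtype=np.float32))
    opt = nn.Adam([p], lr=0.2)
    for _ in range(300):
        loss = (p * p).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.all(np.abs(p.data) < 1e-2)


def test_backward_handles_deep_graphs():
    # iterative topological sort must not hit the recursion limit
    t = Tensor(np.ones(4, dtype=np.float32), requires_grad=True)
    acc = t
    for _ in range(3000):
        acc = acc + t * 0.001
    acc.sum().backward()
    assert t.grad is not None and np.all(np.isfinite(t.grad))
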