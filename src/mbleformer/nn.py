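"""Compact NumPy neural-network core: reverse-mode autodiff, layers, Adam.

Everything in this package that learns — the shifted-window encoder, the
multi-scale attention modules, the lesion-enhancement decoder — is built on
the small tensor engine defined here.  Tensors wrap float32 ndarrays and
record a backward closure per operation; ``Tensor.backward`` runs the tape in
reverse topological order.  The layer zoo is deliberately minimal: 2-D
convolution (with dilation), linear, layer/batch normalisation, bilinear
upsampling and the pointwise nonlinearities, plus an Adam optimiser.

Design constraints:

* float32 throughout; gradients accumulate in float32.
* Convolution is evaluated as a sum over kernel taps (at most 9 for the 3x3
  kernels used here), each tap a single ``tensordot`` — no im2col buffers.
* Bilinear resampling is expressed as two precomputed 1-D interpolation
  matrices, so its adjoint is exact (transpose), and constants are preserved
  (rows sum to 1).
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "Linear",
    "LayerNorm",
    "BatchNorm2d",
    "Adam",
    "concat",
    "sigmoid",
    "relu",
    "softmax",
    "bilinear_upsample",
    "trunc_normal",
]

_FLOAT = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=_FLOAT)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A float32 ndarray plus an autodiff tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=_FLOAT, copy=True)
            if self.grad.shape != self.data.shape:  # scalar broadcast seed
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _node(self, data: np.ndarray, parents: tuple, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs here can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=_FLOAT))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
                node._backward = None
                node._prev = ()

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out = self._node(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            if self.requires_grad:
                self._accum(-out.grad)

        out = self._node(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = self._node(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                g = -out.grad * self.data / (other.data * other.data)
                other._accum(_unbroadcast(g, other.data.shape))

        out = self._node(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        out = self._node(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward():
            if self.requires_grad:
                g = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                g = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                other._accum(_unbroadcast(g, other.data.shape))

        out = self._node(out_data, (self, other), backward)
        return out

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(old))

        out = self._node(out_data, (self,), backward)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        out = self._node(out_data, (self,), backward)
        return out

    def __getitem__(self, idx):
        out_data = self.data[idx]
        fancy = isinstance(idx, (np.ndarray, list)) or (
            isinstance(idx, tuple)
            and any(isinstance(i, (np.ndarray, list)) for i in idx))

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                if fancy:  # repeated indices must accumulate
                    np.add.at(g, idx, out.grad)
                else:
                    g[idx] += out.grad
                self._accum(g)

        out = self._node(out_data, (self,), backward)
        return out

    def pad2d(self, top: int, bottom: int, left: int, right: int):
        """Zero-pad the trailing two (spatial) axes."""
        widths = [(0, 0)] * (self.data.ndim - 2) + [(top, bottom), (left, right)]
        out_data = np.pad(self.data, widths)

        def backward():
            if self.requires_grad:
                sl = [slice(None)] * (self.data.ndim - 2)
                sl += [slice(top, out.grad.shape[-2] - bottom),
                       slice(left, out.grad.shape[-1] - right)]
                self._accum(out.grad[tuple(sl)])

        out = self._node(out_data, (self,), backward)
        return out

    def roll(self, shifts: tuple[int, int], axes: tuple[int, int] = (-2, -1)):
        out_data = np.roll(self.data, shifts, axis=axes)

        def backward():
            if self.requires_grad:
                self._accum(np.roll(out.grad, tuple(-s for s in shifts), axis=axes))

        out = self._node(out_data, (self,), backward)
        return out

    # -- reductions & pointwise -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = self._node(np.asarray(out_data, dtype=_FLOAT), (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out = self._node(out_data, (self,), backward)
        return out

    def log(self):
        out_data = np.log(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out = self._node(out_data, (self,), backward)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = self._node(out_data, (self,), backward)
        return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(int(lo), int(hi))
                t._accum(out.grad[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward():
        if x.requires_grad:
            x._accum(out.grad * s * (1.0 - s))

    out = x._node(s.astype(_FLOAT), (x,), backward)
    return out


def relu(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    mask = x.data > 0

    def backward():
        if x.requires_grad:
            x._accum(out.grad * mask)

    out = x._node(x.data * mask, (x,), backward)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # the max-shift is a constant w.r.t. differentiation
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           padding: int, dilation: int = 1,
           pad_mode: str = "zeros") -> Tensor:
    """Stride-1 2-D convolution, NCHW layout, 'same' achieved via padding.

    Evaluated tap-by-tap: one tensordot per kernel element, which is fast for
    the small (1x1/3x3) kernels this package uses and keeps memory flat.
    """
    x = Tensor._lift(x)
    kh, kw = weight.data.shape[2], weight.data.shape[3]
    if pad_mode == "zeros":
        xp = x.pad2d(padding, padding, padding, padding) if padding else x
    elif pad_mode == "replicate":
        widths = [(0, 0), (0, 0), (padding, padding), (padding, padding)]
        xp = Tensor(np.pad(x.data, widths, mode="edge"))
        # replicate padding is only used in inference-style symmetry checks
    else:
        raise ValueError(f"unknown pad_mode {pad_mode!r}")

    B, C, Hp, Wp = xp.data.shape
    OH = Hp - dilation * (kh - 1)
    OW = Wp - dilation * (kw - 1)
    if OH <= 0 or OW <= 0:
        raise ValueError("input smaller than dilated kernel")

    out_data = np.zeros((B, weight.data.shape[0], OH, OW), dtype=_FLOAT)
    for u in range(kh):
        for v in range(kw):
            xs = xp.data[:, :, u * dilation:u * dilation + OH,
                         v * dilation:v * dilation + OW]
            # (Cout, Cin) . (B, Cin, OH, OW) -> (Cout, B, OH, OW)
            out_data += np.tensordot(weight.data[:, :, u, v], xs,
                                     axes=([1], [1])).transpose(1, 0, 2, 3)
    if bias is not None:
        out_data += bias.data.reshape(1, -1, 1, 1)

    parents = tuple(p for p in (xp, weight, bias) if p is not None)

    def backward():
        g = out.grad
        if weight.requires_grad:
            dW = np.zeros_like(weight.data)
            for u in range(kh):
                for v in range(kw):
                    xs = xp.data[:, :, u * dilation:u * dilation + OH,
                                 v * dilation:v * dilation + OW]
                    dW[:, :, u, v] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
            weight._accum(dW)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if xp.requires_grad:
            dx = np.zeros_like(xp.data)
            for u in range(kh):
                for v in range(kw):
                    dx[:, :, u * dilation:u * dilation + OH,
                       v * dilation:v * dilation + OW] += np.tensordot(
                        weight.data[:, :, u, v], g, axes=([0], [1])
                    ).transpose(1, 0, 2, 3)
            xp._accum(dx)

    out = Tensor(out_data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# bilinear resampling
# ---------------------------------------------------------------------------


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel-centre convention)."""
    M = np.zeros((n_out, n_in), dtype=_FLOAT)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(math.floor(src))
        hi = min(lo + 1, n_in - 1)
        w = src - lo
        M[i, lo] += 1.0 - w
        M[i, hi] += w
    return M


def bilinear_upsample(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling by an integer factor on the two trailing axes."""
    x = Tensor._lift(x)
    B, C, H, W = x.data.shape
    Mh = _interp_matrix(H * factor, H)
    Mw = _interp_matrix(W * factor, W)
    # rows (Mh @ .) then columns (. @ Mw.T), broadcast over batch/channel
    out_data = np.matmul(np.matmul(Mh, x.data), Mw.T)

    def backward():
        if x.requires_grad:
            x._accum(np.matmul(np.matmul(Mh.T, out.grad), Mw))

    out = x._node(out_data, (x,), backward)
    return out


def adaptive_avg_pool(x: Tensor, axis: int) -> Tensor:
    """Mean over one spatial axis, keepdims (directional pooling)."""
    return x.mean(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal at +/- 2 std via resampling."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out.astype(_FLOAT)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container with named-parameter traversal."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                out[f"__bnstat{i}.mean"] = m.running_mean.copy()
                out[f"__bnstat{i}.var"] = m.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=_FLOAT).reshape(p.data.shape)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"__bnstat{i}.mean"], dtype=_FLOAT)
                m.running_var = np.asarray(state[f"__bnstat{i}.var"], dtype=_FLOAT)

    def param_checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """3x3/1x1 convolution with He (fan-in) initialisation."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dilation: int = 1,
                 bias: bool = True, padding: int | None = None):
        super().__init__()
        fan_in = c_in * kernel * kernel
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (c_out, c_in, kernel, kernel)).astype(_FLOAT))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.dilation = dilation
        # 'same' padding for stride-1 odd kernels
        self.padding = dilation * (kernel - 1) // 2 if padding is None else padding

    def forward(self, x: Tensor, pad_mode: str = "zeros") -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding,
                      self.dilation, pad_mode)


class LayerNorm(Module):
    """Normalisation over the trailing axis (token channel dim)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * ((var + self.eps) ** -0.5)
        return xhat * self.weight + self.bias


class BatchNorm2d(Module):
    """Batch norm over (batch, H, W); momentum 0.3 so running statistics
    track batch statistics quickly in short training runs."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.3):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_FLOAT)
        self.running_var = np.ones(channels, dtype=_FLOAT)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1))
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xc = x - mu
        xhat = xc * ((var + self.eps) ** -0.5)
        return (xhat * self.weight.reshape(1, -1, 1, 1)
                + self.bias.reshape(1, -1, 1, 1))


class Adam:
    """Adam with per-step learning rate supplied by the caller."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
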