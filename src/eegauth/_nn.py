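"""Compact CPU neural-network engine (numpy, float32).

Implements exactly the layer vocabulary the authentication networks need:
N-dimensional stride-1 convolution (1D/2D/3D), batch normalization, leaky
ReLU, non-overlapping max pooling, dropout, linear layers, a parallel-branch
container with channel concatenation, softmax cross-entropy, and SGD/Adam.

Convolutions take one of two routes: small kernels (<= 96 taps) run as
channels-last shift-and-matmul — one zero-copy batched GEMM per kernel
tap — while large kernels fall back to chunked im2col GEMMs that keep the
big 3D networks inside a modest memory envelope (the input gradient there
is the full correlation with the channel-swapped, spatially flipped
kernel, routed through the same im2col path).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_DTYPE = np.float32
# im2col chunk budget (elements); keeps any single column matrix ~64 MB.
_CHUNK_ELEMS = 16_000_000


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _prod(t: Sequence[int]) -> int:
    out = 1
    for v in t:
        out *= int(v)
    return out


def _corr(x: np.ndarray, wmat: np.ndarray, ksizes: tuple[int, ...],
          pads: tuple[int, ...], out_channels: int,
          cols_consumer=None) -> np.ndarray:
    """Stride-1 cross-correlation of (N, C, *S) with a (C_out, C*prod(k))
    weight matrix, chunked along the first spatial output axis.

    ``cols_consumer(n, s0, e0, cols, rows_shape)`` is invoked with every
    im2col block, letting the backward pass accumulate weight gradients
    without materializing the full column matrix.
    """
    nd = len(ksizes)
    n_batch, c_in = x.shape[:2]
    xp = x if not any(pads) else \
        np.pad(x, [(0, 0), (0, 0)] + [(p, p) for p in pads])
    space = xp.shape[2:]
    out = tuple(space[i] - ksizes[i] + 1 for i in range(nd))
    if any(o <= 0 for o in out):
        raise ValueError(f"kernel {ksizes} larger than padded input {space}")
    colwidth = c_in * _prod(ksizes)
    rest = _prod(out[1:]) if nd > 1 else 1
    rows = _prod(out)
    # fast path: whole batch in one GEMM when it fits the chunk budget
    if n_batch * rows * colwidth <= _CHUNK_ELEMS:
        win = sliding_window_view(xp, ksizes, axis=tuple(range(2, 2 + nd)))
        cols = np.moveaxis(win, 1, 1 + nd).reshape(-1, colwidth)
        cols = np.ascontiguousarray(cols, dtype=_DTYPE)
        if cols_consumer is not None:
            cols_consumer(None, 0, out[0], cols)
        if wmat is None:
            return None
        block = cols @ wmat.T                       # (N*rows, C_out)
        y = block.reshape((n_batch, rows, out_channels))
        return np.ascontiguousarray(
            np.moveaxis(y, 2, 1).reshape((n_batch, out_channels) + out))
    chunk0 = max(1, min(out[0], _CHUNK_ELEMS // max(1, colwidth * rest)))
    y = (np.empty((n_batch, out_channels) + out, dtype=_DTYPE)
         if wmat is not None else None)
    spatial_axes = tuple(range(1, 1 + nd))
    for n in range(n_batch):
        for s0 in range(0, out[0], chunk0):
            e0 = min(out[0], s0 + chunk0)
            sub = xp[n, :, s0:e0 + ksizes[0] - 1]
            win = sliding_window_view(sub, ksizes, axis=spatial_axes)
            # (C, o0c, o1.., *k) -> (o0c, o1.., C, *k) -> rows x colwidth
            cols = np.moveaxis(win, 0, nd).reshape(-1, colwidth)
            cols = np.ascontiguousarray(cols, dtype=_DTYPE)
            if cols_consumer is not None:
                cols_consumer(n, s0, e0, cols)
            if wmat is not None:
                block = cols @ wmat.T                   # (rows, C_out)
                y[n, :, s0:e0] = block.T.reshape(
                    (out_channels, e0 - s0) + out[1:])
    return y


def _tap_iter(ksizes: tuple[int, ...]):
    import itertools
    return itertools.product(*[range(k) for k in ksizes])


def _tap_forward(xc: np.ndarray, w: np.ndarray,
                 out: tuple[int, ...]) -> np.ndarray:
    """Shift-and-matmul convolution on channels-last data: one zero-copy
    batched GEMM per kernel tap.

    ``xc`` is the padded input in channels-last layout (N, *Sp, C); the
    returned output is channels-last (N, *out, C_out).  Avoids the large
    strided im2col copy that dominates for small kernels.
    """
    n = xc.shape[0]
    c_out = w.shape[0]
    # (*k, C_in, C_out) so wT[taps] right-multiplies channel vectors
    w_t = np.ascontiguousarray(np.moveaxis(w, (0, 1), (-1, -2)))
    y = np.zeros((n,) + out + (c_out,), dtype=_DTYPE)
    for taps in _tap_iter(w.shape[2:]):
        sl = (slice(None),) + tuple(
            slice(j, j + o) for j, o in zip(taps, out)) + (slice(None),)
        y += xc[sl] @ w_t[taps]
    return y


def _tap_backward(xc: np.ndarray, w: np.ndarray, dy_c: np.ndarray,
                  out: tuple[int, ...], wgrad: np.ndarray) -> np.ndarray:
    """Gradients for the tap path (channels-last): returns d(xc) and
    accumulates the weight gradient."""
    w_t = np.ascontiguousarray(np.moveaxis(w, (0, 1), (-1, -2)))
    dxc = np.zeros_like(xc)
    lead = tuple(range(dy_c.ndim - 2))
    for taps in _tap_iter(w.shape[2:]):
        sl = (slice(None),) + tuple(
            slice(j, j + o) for j, o in zip(taps, out)) + (slice(None),)
        dxc[sl] += dy_c @ w_t[taps].T
        g = np.matmul(np.swapaxes(xc[sl], -1, -2), dy_c)   # (..., C, C_out)
        wgrad[(slice(None), slice(None)) + taps] += g.sum(axis=lead).T
    return dxc


def _flip_swap(w: np.ndarray) -> np.ndarray:
    """(C_out, C_in, *k) -> (C_in, C_out, *k) with spatial axes reversed."""
    nd = w.ndim - 2
    flipped = w[(slice(None), slice(None)) + (slice(None, None, -1),) * nd]
    return np.ascontiguousarray(np.swapaxes(flipped, 0, 1))


class ConvNd(Layer):
    """Stride-1 convolution over 1-3 spatial axes with per-axis zero padding."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, ...], padding: tuple[int, ...] | None = None):
        kernel = tuple(int(k) for k in kernel)
        padding = tuple(int(p) for p in (padding or (0,) * len(kernel)))
        if len(padding) != len(kernel):
            raise ValueError("padding rank must match kernel rank")
        if any(p > k - 1 for p, k in zip(padding, kernel)):
            raise ValueError("padding may not exceed kernel-1 per axis")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.padding = kernel, padding
        self.weight = Parameter(np.zeros((out_channels, in_channels) + kernel))
        self.bias = Parameter(np.zeros(out_channels))
        self._x: np.ndarray | None = None

    def parameters(self):
        return [self.weight, self.bias]

    @property
    def fan_in(self) -> int:
        return self.in_channels * _prod(self.kernel)

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        """(C, *S) -> (C_out, *S_out); raises if the kernel does not fit."""
        if in_shape[0] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {in_shape[0]}")
        space = tuple(s + 2 * p - k + 1 for s, p, k in
                      zip(in_shape[1:], self.padding, self.kernel))
        if any(s <= 0 for s in space):
            raise ValueError(
                f"kernel {self.kernel} exhausts spatial input {in_shape[1:]}")
        return (self.out_channels,) + space

    @property
    def _use_taps(self) -> bool:
        return _prod(self.kernel) <= 96

    def _padded(self, x):
        if not any(self.padding):
            return x
        return np.pad(x, [(0, 0), (0, 0)] +
                      [(p, p) for p in self.padding])

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        self._x = None
        if self._use_taps:
            xp = self._padded(x)
            out = tuple(s - k + 1 for s, k in zip(xp.shape[2:], self.kernel))
            if any(o <= 0 for o in out):
                raise ValueError(
                    f"kernel {self.kernel} larger than padded input "
                    f"{xp.shape[2:]}")
            xc = np.ascontiguousarray(np.moveaxis(xp, 1, -1))
            if train:
                self._x = xc
            y = np.ascontiguousarray(
                np.moveaxis(_tap_forward(xc, self.weight.value, out), -1, 1))
        else:
            self._x = x if train else None
            wmat = self.weight.value.reshape(self.out_channels, -1)
            y = _corr(x, wmat, self.kernel, self.padding, self.out_channels)
        y += self.bias.value.reshape((1, -1) + (1,) * len(self.kernel))
        return y

    def backward(self, dy):
        x = self._x
        if x is None:
            raise RuntimeError("backward before training forward")
        dy = np.ascontiguousarray(dy, dtype=_DTYPE)
        nd = len(self.kernel)
        axes = (0,) + tuple(range(2, 2 + nd))
        self.bias.grad += dy.sum(axis=axes)

        if self._use_taps:      # x holds the channels-last padded input
            out = dy.shape[2:]
            dy_c = np.ascontiguousarray(np.moveaxis(dy, 1, -1))
            dxc = _tap_backward(x, self.weight.value, dy_c, out,
                                self.weight.grad)
            self._x = None
            dxp = np.moveaxis(dxc, -1, 1)
            if any(self.padding):
                core = (slice(None), slice(None)) + tuple(
                    slice(p, s - p)
                    for p, s in zip(self.padding, dxp.shape[2:]))
                dxp = dxp[core]
            return np.ascontiguousarray(dxp)

        # GEMM path: accumulate dy_block^T @ cols over im2col chunks
        wgrad = self.weight.grad.reshape(self.out_channels, -1)

        def consume(n, s0, e0, cols):
            if n is None:       # fast path: cols covers the whole batch
                nb = dy.shape[0]
                dyb = np.moveaxis(dy.reshape(nb, self.out_channels, -1),
                                  1, 2).reshape(-1, self.out_channels)
                np.add(wgrad, np.ascontiguousarray(dyb).T @ cols, out=wgrad)
            else:
                block = dy[n, :, s0:e0].reshape(self.out_channels, -1)
                np.add(wgrad, block @ cols, out=wgrad)

        _corr(x, None, self.kernel, self.padding, self.out_channels,
              cols_consumer=consume)

        # input gradient: full correlation with flipped, channel-swapped kernel
        w2 = _flip_swap(self.weight.value).reshape(self.in_channels, -1)
        tpad = tuple(k - 1 - p for k, p in zip(self.kernel, self.padding))
        dx = _corr(dy, w2, self.kernel, tpad, self.in_channels)
        self._x = None
        return dx


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int):
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(np.zeros((out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    @property
    def fan_in(self) -> int:
        return self.in_features

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        self._x = x if train else None
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy):
        dy = np.ascontiguousarray(dy, dtype=_DTYPE)
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        dx = dy @ self.weight.value
        self._x = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over batch + spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        axes = (0,) + tuple(range(2, x.ndim))
        shape = (1, -1) + (1,) * (x.ndim - 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        if train:
            self._cache = (xhat, inv_std, axes, shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dy):
        xhat, inv_std, axes, shape = self._cache
        self._cache = None
        m = _prod([dy.shape[i] for i in axes])
        dsum = dy.sum(axis=axes)
        dxhat_sum = (dy * xhat).sum(axis=axes)
        self.gamma.grad += dxhat_sum
        self.beta.grad += dsum
        g = (self.gamma.value * inv_std).reshape(shape)
        dx = g * (dy - (dsum.reshape(shape) + xhat * dxhat_sum.reshape(shape)) / m)
        return dx.astype(_DTYPE, copy=False)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dy):
        dy = np.where(self._mask, dy, self.slope * dy)
        self._mask = None
        return dy


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float = 0.4):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p).astype(_DTYPE) / (1 - self.p)
        self._mask = mask
        return x * mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dy = dy * self._mask
        self._mask = None
        return dy


class MaxPool(Layer):
    """Non-overlapping max pooling (stride = pool size, floor mode)."""

    def __init__(self, pool: tuple[int, ...]):
        self.pool = tuple(int(p) for p in pool)
        if any(p < 1 for p in self.pool):
            raise ValueError("pool sizes must be >= 1")
        self._cache = None

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        space = tuple(s // p for s, p in zip(in_shape[1:], self.pool))
        if any(s == 0 for s in space):
            raise ValueError(f"pool {self.pool} exhausts spatial input {in_shape[1:]}")
        return (in_shape[0],) + space

    def forward(self, x, train=False):
        nd = len(self.pool)
        n, c = x.shape[:2]
        space = x.shape[2:]
        out = tuple(s // p for s, p in zip(space, self.pool))
        if any(o == 0 for o in out):
            raise ValueError(f"pool {self.pool} exhausts spatial input {space}")
        crop = x[(slice(None), slice(None)) +
                 tuple(slice(0, o * p) for o, p in zip(out, self.pool))]
        inter = []
        for o, p in zip(out, self.pool):
            inter += [o, p]
        r = crop.reshape((n, c) + tuple(inter))
        perm = [0, 1] + [2 + 2 * i for i in range(nd)] + [3 + 2 * i for i in range(nd)]
        windows = r.transpose(perm).reshape((n, c) + out + (_prod(self.pool),))
        idx = windows.argmax(axis=-1)
        y = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, out, idx)
        return np.ascontiguousarray(y)

    def backward(self, dy):
        in_shape, out, idx = self._cache
        self._cache = None
        nd = len(self.pool)
        n, c = in_shape[:2]
        windows = np.zeros((n, c) + out + (_prod(self.pool),), dtype=_DTYPE)
        np.put_along_axis(windows, idx[..., None], dy[..., None], axis=-1)
        inter_shape = (n, c) + tuple(v for o in zip(out, self.pool) for v in o)
        perm = [0, 1] + [2 + 2 * i for i in range(nd)] + [3 + 2 * i for i in range(nd)]
        inv = np.argsort(perm)
        r = windows.reshape((n, c) + out + self.pool).transpose(inv)
        dx = np.zeros(in_shape, dtype=_DTYPE)
        dx[(slice(None), slice(None)) +
           tuple(slice(0, o * p) for o, p in zip(out, self.pool))] = \
            r.reshape((n, c) + tuple(o * p for o, p in zip(out, self.pool)))
        return dx


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Branches(Layer):
    """Parallel branches over a shared input, concatenated on the channel axis.

    All branches must emit identical spatial dims (enforced at run time;
    the network builder also enforces it analytically).
    """

    def __init__(self, branches: list[Sequential]):
        self.branches = list(branches)
        self.capture = False
        self.captured: list[np.ndarray] | None = None
        self._widths = None

    def parameters(self):
        return [p for b in self.branches for p in b.parameters()]

    def forward(self, x, train=False):
        outs = [b.forward(x, train) for b in self.branches]
        spatial = {o.shape[2:] for o in outs}
        if len(spatial) != 1:
            raise ValueError(f"branch outputs misaligned: {sorted(spatial)}")
        if self.capture:
            self.captured = [o.copy() for o in outs]
        self._widths = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        dx = None
        start = 0
        for b, w in zip(self.branches, self._widths):
            part = b.backward(dy[:, start:start + w])
            dx = part if dx is None else dx + part
            start += w
        return dx


def kaiming_uniform_(param: Parameter, fan_in: int, rng: np.random.Generator) -> None:
    """U(-b, b) with b = sqrt(6 / fan_in) (leaky-ReLU gain convention)."""
    bound = math.sqrt(6.0 / fan_in)
    param.value[...] = rng.uniform(-bound, bound, size=param.value.shape)


class Network:
    """A layer stack with deterministic initialization and a softmax-2 head.

    ``forward`` returns logits; :meth:`predict_proba` applies the softmax.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...]):
        self.stack = Sequential(layers)
        self.input_shape = tuple(input_shape)   # (C, *S) without batch axis

    # -- parameters -------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        return self.stack.parameters()

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    def _walk(self, layer=None):
        layer = layer if layer is not None else self.stack
        yield layer
        for child in getattr(layer, "layers", []) + getattr(layer, "branches", []):
            yield from self._walk(child)

    def initialize(self, seed: int) -> "Network":
        """Kaiming-uniform conv/linear weights, zero biases, seeded dropout."""
        rng = np.random.default_rng(seed)
        for l in self._walk():
            if isinstance(l, (ConvNd, Linear)):
                kaiming_uniform_(l.weight, l.fan_in, rng)
                l.bias.value[...] = 0
            elif isinstance(l, Dropout):
                l.rng = np.random.default_rng(rng.integers(2 ** 31))
        return self

    # -- execution --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                capture: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected input {self.input_shape}, got {x.shape[1:]}")
        for l in self._walk():
            if isinstance(l, Branches):
                l.capture = capture
        return self.stack.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.stack.backward(dlogits)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def branch_outputs(self) -> list[list[np.ndarray]]:
        """Captured per-module branch activations from the last
        ``forward(..., capture=True)`` call, outermost module first."""
        return [l.captured for l in self._walk()
                if isinstance(l, Branches) and l.captured is not None]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -float(np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(_DTYPE)


class SGD:
    def __init__(self, params: list[Parameter], lr: float):
        self.params, self.lr = params, lr

    def step(self) -> None:
        for p in self.params:
            p.value -= self.lr * p.grad


class Adam:
    def __init__(self, params: list[Parameter], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params, self.lr = params, lr
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad ** 2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def make_optimizer(name: str, params: list[Parameter], lr: float):
    name = name.lower()
    if name == "adam":
        return Adam(params, lr)
    if name == "sgd":
        return SGD(params, lr)
    raise ValueError(f"unknown optimizer {name!r}")
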