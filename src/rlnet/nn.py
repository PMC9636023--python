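"""Minimal reverse-mode autodiff for small 3D convolutional networks.

The deconvolution network trained here is tiny (tens of thousands of
parameters, a dozen conv layers), so rather than depending on a deep-learning
framework this module provides exactly the primitives it needs on numpy
arrays: 3x3x3 same-padded convolution (im2col + BLAS matmul), 2x stride-2
transpose convolution, 2x average pooling, batch normalization, softplus,
elementwise arithmetic with channel broadcasting, reductions, and Adam.

Tensors are float32 with layout [N, C, D, H, W]. Gradients are accumulated
on ``Tensor.grad`` by ``Tensor.backward()`` in reverse topological order.
``no_grad()`` disables graph construction for inference.
"""

from __future__ import annotations

import contextlib
from itertools import product
from typing import Iterable

import numpy as np

__all__ = [
    "Tensor", "no_grad", "add", "sub", "mul", "div", "concat", "mean",
    "channel_mean", "softplus", "avg_pool2", "log", "square", "clamp_min",
    "Conv3d", "ConvTranspose3d2x", "BatchNorm3d", "Adam",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev, _grad_enabled = _grad_enabled, False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad and _grad_enabled
        self._backward = None
        self._prev: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g


def _wrap(data, parents: Iterable[Tensor], backward) -> Tensor:
    parents = tuple(parents)
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._prev = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` along broadcast axes."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise arithmetic -------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))
    return _wrap(a.data + b.data, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(-g, b.shape))
    return _wrap(a.data - b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))
    return _wrap(a.data * b.data, (a, b), bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    inv = 1.0 / b.data

    def bw(g):
        a._accum(_unbroadcast(g * inv, a.shape))
        b._accum(_unbroadcast(-g * a.data * inv * inv, b.shape))
    return _wrap(a.data * inv, (a, b), bw)


def add_const(a: Tensor, c: float) -> Tensor:
    return _wrap(a.data + np.float32(c), (a,), lambda g: a._accum(g))


def mul_const(a: Tensor, c: float) -> Tensor:
    return _wrap(a.data * np.float32(c), (a,), lambda g: a._accum(g * np.float32(c)))


def log(a: Tensor) -> Tensor:
    def bw(g):
        a._accum(g / a.data)
    return _wrap(np.log(a.data), (a,), bw)


def square(a: Tensor) -> Tensor:
    def bw(g):
        a._accum(2.0 * g * a.data)
    return _wrap(a.data * a.data, (a,), bw)


def clamp_min(a: Tensor, lo: float) -> Tensor:
    mask = a.data > lo

    def bw(g):
        a._accum(g * mask)
    return _wrap(np.maximum(a.data, np.float32(lo)), (a,), bw)


# -- reductions and shape ops ----------------------------------------------

def mean(a: Tensor, axes=None, keepdims: bool = False) -> Tensor:
    axes = tuple(range(a.data.ndim)) if axes is None else tuple(axes)
    n = float(np.prod([a.shape[ax] for ax in axes]))
    out_data = a.data.mean(axis=axes, keepdims=keepdims)

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        a._accum(np.broadcast_to(g / n, a.shape))
    return _wrap(out_data, (a,), bw)


def channel_mean(a: Tensor) -> Tensor:
    """Channel-wise average C_AVE: [N, C, ...] -> [N, 1, ...]."""
    return mean(a, axes=(1,), keepdims=True)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    return _wrap(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def softplus(a: Tensor) -> Tensor:
    from ._conv_kernels import softplus_fwd
    out_data, sig = softplus_fwd(a.data)

    def bw(g):
        a._accum(g * sig)
    return _wrap(out_data, (a,), bw)


def avg_pool2(a: Tensor) -> Tensor:
    """2x average pooling on [N, C, D, H, W]; dims must be even."""
    N, C, D, H, W = a.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"avg_pool2 requires even spatial dims, got {(D, H, W)}")
    r = a.data.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
    out_data = r.mean(axis=(3, 5, 7))

    def bw(g):
        gx = np.empty_like(a.data)
        gx.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)[:] = \
            (g / 8.0)[:, :, :, None, :, None, :, None]
        a._accum(gx)
    return _wrap(out_data, (a,), bw)


# -- layers -----------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters stay trainable under no_grad


class Conv3d:
    """3x3x3 convolution, stride 1, zero 'same' padding, via im2col."""

    K = 3

    def __init__(self, in_channels: int, out_channels: int, weight=None, bias=None):
        self.in_channels, self.out_channels = in_channels, out_channels
        kshape = (out_channels, in_channels, self.K, self.K, self.K)
        self.weight = Parameter(np.zeros(kshape, np.float32) if weight is None else weight)
        self.bias = Parameter(np.zeros(out_channels, np.float32) if bias is None else bias)

    def parameters(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        from ._conv_kernels import conv3d_dw, conv3d_dx, conv3d_fwd
        N, C, D, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        y = conv3d_fwd(xp, self.weight.data, self.bias.data)

        weight, bias = self.weight, self.bias

        def bw(g):
            g = np.ascontiguousarray(g, dtype=np.float32)
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3, 4)))
            if weight.requires_grad:
                weight._accum(conv3d_dw(xp, g))
            if x.requires_grad:
                x._accum(conv3d_dx(g, self.weight.data))
        return _wrap(y, (x, self.weight, self.bias), bw)


class ConvTranspose3d2x:
    """Transpose convolution with 2x2x2 kernel and stride 2 (2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, weight=None, bias=None):
        self.in_channels, self.out_channels = in_channels, out_channels
        kshape = (out_channels, in_channels, 2, 2, 2)
        self.weight = Parameter(np.zeros(kshape, np.float32) if weight is None else weight)
        self.bias = Parameter(np.zeros(out_channels, np.float32) if bias is None else bias)

    def parameters(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        N, C, D, H, W = x.shape
        O = self.out_channels
        x2 = x.data.reshape(N, C, -1)
        y = np.empty((N, O, 2 * D, 2 * H, 2 * W), np.float32)
        for i, j, k in product(range(2), repeat=3):
            yo = np.matmul(self.weight.data[:, :, i, j, k], x2)  # [N, O, V]
            y[:, :, i::2, j::2, k::2] = yo.reshape(N, O, D, H, W)
        y += self.bias.data[None, :, None, None, None]

        weight, bias = self.weight, self.bias

        def bw(g):
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3, 4)))
            gx = np.zeros_like(x.data) if x.requires_grad else None
            for i, j, k in product(range(2), repeat=3):
                go = g[:, :, i::2, j::2, k::2].reshape(N, O, -1)
                if weight.requires_grad:
                    dw = np.matmul(go, x2.transpose(0, 2, 1)).sum(axis=0)  # [O, C]
                    weight.grad = weight.grad if weight.grad is not None else \
                        np.zeros_like(weight.data)
                    weight.grad[:, :, i, j, k] += dw
                if gx is not None:
                    gx += np.matmul(self.weight.data[:, :, i, j, k].T, go).reshape(x.shape)
            if gx is not None:
                x._accum(gx)
        return _wrap(y, (x, self.weight, self.bias), bw)


class BatchNorm3d:
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, np.float32))
        self.beta = Parameter(np.zeros(channels, np.float32))
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = (0, 2, 3, 4)
        if training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        bshape = (1, self.channels, 1, 1, 1)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(bshape)) * istd.reshape(bshape)
        y = self.gamma.data.reshape(bshape) * xhat + self.beta.data.reshape(bshape)

        gamma, beta = self.gamma, self.beta
        m = x.data.size / self.channels

        def bw(g):
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if x.requires_grad:
                gh = g * gamma.data.reshape(bshape)
                if training:
                    # standard batch-norm input gradient with batch statistics
                    s1 = gh.sum(axis=axes).reshape(bshape)
                    s2 = (gh * xhat).sum(axis=axes).reshape(bshape)
                    gx = (gh - s1 / m - xhat * s2 / m) * istd.reshape(bshape)
                else:
                    gx = gh * istd.reshape(bshape)
                x._accum(gx)
        return _wrap(y, (x, self.gamma, self.beta), bw)

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


# -- optimizer ---------------------------------------------------------------

class Adam:
    """Adam with externally supplied per-step learning rate."""

    def __init__(self, params: list[Parameter], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
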