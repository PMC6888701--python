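"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based autograd: each op builds a closure that
propagates gradients to its inputs, and ``Tensor.backward`` walks the tape
in reverse topological order.  Only the operations needed by the networks
in this package are provided (convolutions, batch norm, pooling with
indices, activations, losses).  Arrays are NCHW throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "mul", "concat", "reshape", "linear",
    "conv2d", "depthwise_conv2d", "conv_transpose2d", "batchnorm2d",
    "relu", "leaky_relu", "tanh", "sigmoid", "dropout",
    "maxpool2x2", "maxunpool2x2", "avgpool2x2", "global_avg_pool",
    "cross_entropy_logits", "bce_logits", "mse_loss", "softmax",
]


class Tensor:
    """An array node on the autograd tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False, _prev=()):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _needs(*tensors):
    return any(t.requires_grad or t._prev for t in tensors)


def _make(data, parents, backward):
    out = Tensor(data)
    if _needs(*parents):
        out._prev = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------- basic ops

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))
    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, s: float) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s)
    return _make(a.data * s, (a,), backward)


def concat(tensors, axis=1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])
    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))
    return _make(a.data.reshape(shape), (a,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (B, F) @ w (F, O) + b (O,)."""
    y = x.data @ w.data
    if b is not None:
        y = y + b.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ w.data.T)
        if w.requires_grad:
            w._accumulate(x.data.T @ g)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))
    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, backward)


# --------------------------------------------------------------- conv cores
# Loops run over the (small) kernel footprint; every iteration is one large
# tensordot, which keeps the work inside BLAS.

def _conv_fwd(x, w, stride, pad):
    B, C, H, W = x.shape
    O, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    oh = (H + 2 * pad - kh) // stride + 1
    ow = (W + 2 * pad - kw) // stride + 1
    y = np.zeros((B, O, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            y += np.tensordot(xs, w[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
    return y


def _conv_grad_x(gy, w, x_shape, stride, pad):
    B, C, H, W = x_shape
    O, _, kh, kw = w.shape
    oh, ow = gy.shape[2:]
    gxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=gy.dtype)
    for i in range(kh):
        for j in range(kw):
            contrib = np.tensordot(gy, w[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
            gxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += contrib
    return gxp[:, :, pad:pad + H, pad:pad + W] if pad else gxp


def _conv_grad_w(x, gy, w_shape, stride, pad):
    O, C, kh, kw = w_shape
    oh, ow = gy.shape[2:]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    gw = np.zeros(w_shape, dtype=gy.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            gw[:, :, i, j] = np.tensordot(gy, xs, axes=([0, 2, 3], [0, 2, 3]))
    return gw


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, pad=0) -> Tensor:
    """2-D convolution; w has shape (out_ch, in_ch, kh, kw)."""
    y = _conv_fwd(x.data, w.data, stride, pad)
    if b is not None:
        y = y + b.data[None, :, None, None]

    def backward(g):
        if x.requires_grad:
            x._accumulate(_conv_grad_x(g, w.data, x.data.shape, stride, pad))
        if w.requires_grad:
            w._accumulate(_conv_grad_w(x.data, g, w.data.shape, stride, pad))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, stride=1, pad=0) -> Tensor:
    """Per-channel spatial convolution; w has shape (ch, kh, kw)."""
    B, C, H, W = x.data.shape
    _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    oh = (H + 2 * pad - kh) // stride + 1
    ow = (W + 2 * pad - kw) // stride + 1
    y = np.zeros((B, C, oh, ow), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            y += xs * w.data[None, :, i, j, None, None]

    def backward(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += (
                        g * w.data[None, :, i, j, None, None])
            x._accumulate(gxp[:, :, pad:pad + H, pad:pad + W] if pad else gxp)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    xs = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
                    gw[:, i, j] = (g * xs).sum(axis=(0, 2, 3))
            w._accumulate(gw)
    return _make(y, (x, w), backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=2, pad=1) -> Tensor:
    """Transposed convolution (adjoint of conv2d); w shape (in_ch, out_ch, kh, kw).

    Output spatial size is (H-1)*stride + k - 2*pad, i.e. exactly 2H for the
    4x4/stride-2/pad-1 blocks used by the generator decoder.
    """
    C_in, C_out, kh, kw = w.data.shape
    B, _, H, W = x.data.shape
    oh = (H - 1) * stride + kh - 2 * pad
    ow = (W - 1) * stride + kw - 2 * pad
    y = _conv_grad_x(x.data, w.data, (B, C_out, oh, ow), stride, pad)
    if b is not None:
        y = y + b.data[None, :, None, None]

    def backward(g):
        if x.requires_grad:
            x._accumulate(_conv_fwd(g, w.data, stride, pad))
        if w.requires_grad:
            w._accumulate(_conv_grad_w(g, x.data, w.data.shape, stride, pad))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, backward)


# ------------------------------------------------------------- norm & misc

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
                momentum=0.1, eps=1e-5, training=True) -> Tensor:
    """Channel-wise batch normalization with running statistics.

    ``running_mean``/``running_var`` are plain arrays updated in place when
    ``training`` is true.
    """
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * inv_std[None, :, None, None]
    y = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * gamma.data[None, :, None, None]
            if training:
                n = xd.shape[0] * xd.shape[2] * xd.shape[3]
                s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (gxhat - s1 / n - xhat * s2 / n) * inv_std[None, :, None, None]
            else:
                gx = gxhat * inv_std[None, :, None, None]
            x._accumulate(gx)
    return _make(y, (x, gamma, beta), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)
    return _make(x.data * mask, (x,), backward)


def leaky_relu(x: Tensor, alpha=0.2) -> Tensor:
    mask = x.data > 0
    slope = np.where(mask, 1.0, alpha).astype(x.data.dtype)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * slope)
    return _make(x.data * slope, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (1 - y * y))
    return _make(y, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * y * (1 - y))
    return _make(y, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training=True) -> Tensor:
    if not training or p <= 0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1 - p)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * keep)
    return _make(x.data * keep, (x,), backward)


# ----------------------------------------------------------------- pooling

def _pool_view(xd):
    B, C, H, W = xd.shape
    return xd.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, H // 2, W // 2, 4)


def maxpool2x2(x: Tensor):
    """2x2/stride-2 max pooling. Returns (pooled, indices); indices locate each
    max inside its window and can be replayed by :func:`maxunpool2x2`."""
    v = _pool_view(x.data)
    idx = v.argmax(axis=-1)
    y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
    B, C, H, W = x.data.shape

    def backward(g):
        if x.requires_grad:
            gv = np.zeros((B, C, H // 2, W // 2, 4), dtype=g.dtype)
            np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
            gx = gv.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
            x._accumulate(gx)
    return _make(y, (x,), backward), idx


def maxunpool2x2(x: Tensor, idx) -> Tensor:
    """Places each value at the window position recorded by the paired pool."""
    B, C, H, W = x.data.shape
    v = np.zeros((B, C, H, W, 4), dtype=x.data.dtype)
    np.put_along_axis(v, idx[..., None], x.data[..., None], axis=-1)
    y = v.reshape(B, C, H, W, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, 2 * H, 2 * W)

    def backward(g):
        if x.requires_grad:
            gv = _pool_view(g)
            x._accumulate(np.take_along_axis(gv, idx[..., None], axis=-1)[..., 0])
    return _make(y, (x,), backward)


def avgpool2x2(x: Tensor) -> Tensor:
    v = _pool_view(x.data)
    y = v.mean(axis=-1)

    def backward(g):
        if x.requires_grad:
            B, C, H, W = x.data.shape
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
            x._accumulate(gx)
    return _make(y, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C)."""
    B, C, H, W = x.data.shape
    y = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape))
    return _make(y, (x,), backward)


# ------------------------------------------------------------------ losses

def softmax(z: np.ndarray, axis=-1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy. ``logits`` is (B, K) or (B, K, H, W)
    (per-pixel); ``labels`` holds integer class ids of shape (B,) or (B, H, W)."""
    ld = logits.data
    if ld.ndim == 4:
        ld2 = ld.transpose(0, 2, 3, 1).reshape(-1, ld.shape[1])
        lab = labels.reshape(-1)
    else:
        ld2, lab = ld, labels
    n = ld2.shape[0]
    zmax = ld2.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(ld2 - zmax).sum(axis=1))
    loss = (lse - ld2[np.arange(n), lab]).mean()

    def backward(g):
        if logits.requires_grad:
            p = softmax(ld2, axis=1)
            p[np.arange(n), lab] -= 1.0
            p *= g / n
            if ld.ndim == 4:
                p = p.reshape(ld.shape[0], ld.shape[2], ld.shape[3], ld.shape[1]).transpose(0, 3, 1, 2)
            logits._accumulate(p.astype(ld.dtype))
    return _make(np.asarray(loss, dtype=ld.dtype), (logits,), backward)


def bce_logits(logits: Tensor, target) -> Tensor:
    """Mean binary cross-entropy on logits; ``target`` is an array or scalar."""
    z = logits.data
    t = np.broadcast_to(np.asarray(target, dtype=z.dtype), z.shape)
    loss = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))).mean()

    def backward(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate((s - t) * (g / z.size))
    return _make(np.asarray(loss, dtype=z.dtype), (logits,), backward)


def mse_loss(a: Tensor, b: Tensor) -> Tensor:
    d = a.data - b.data
    loss = np.mean(d * d)

    def backward(g):
        s = 2.0 * g / d.size
        if a.requires_grad:
            a._accumulate(s * d)
        if b.requires_grad:
            b._accumulate(-s * d)
    return _make(np.asarray(loss, dtype=d.dtype), (a, b), backward)
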