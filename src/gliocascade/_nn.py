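"""Minimal NumPy neural-network core with manual backpropagation.

Implements exactly the layers the two networks need — N-D convolution
(same padding, stride 1), 2x max-pooling, nearest-neighbor 2x
upsampling, stride-2 transposed convolution, batch normalization, dense
layers, ELU/ReLU/sigmoid activations — plus Adam with decoupled-style L2
on the convolution/dense weights.

Internal tensor layout is channels-last, ``(B, *spatial, C)``, with 2 or
3 spatial axes; convolutions are computed as one BLAS matmul per kernel
offset, which keeps peak memory at a small multiple of the activation
size (no im2col buffers).  Every layer caches what its backward pass
needs during ``forward(..., train=True)``.

Gradient correctness is established by finite-difference checks in the
test suite; all randomness flows through an explicit ``Generator``.
"""

from __future__ import annotations

import itertools

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "l2")

    def __init__(self, value: np.ndarray, l2: bool = False):
        self.value = value
        self.grad = np.zeros_like(value)
        self.l2 = l2  # weight participates in the L2 penalty


class Layer:
    def params(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class ConvND(Layer):
    """Same-padded stride-1 convolution over 2 or 3 spatial axes.

    Weights are stored as ``(n_offsets, c_in, c_out)`` with one slice
    per kernel offset; parameter count is ``k^nd * c_in * c_out + c_out``.
    """

    def __init__(self, c_in, c_out, k=3, nd=3, rng=None, dtype=np.float32,
                 needs_dx=True):
        self.c_in, self.c_out, self.k, self.nd = c_in, c_out, k, nd
        self.needs_dx = needs_dx  # first layer of a net can skip dx
        self.offsets = list(itertools.product(range(k), repeat=nd))
        fan_in = (k ** nd) * c_in
        scale = np.sqrt(2.0 / fan_in)  # He init (ELU/ReLU nets)
        w = rng.normal(0.0, scale, size=(len(self.offsets), c_in, c_out))
        self.W = Param(w.astype(dtype), l2=True)
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def _pad(self, x):
        p = (self.k - 1) // 2
        if p == 0:
            return x
        pad = [(0, 0)] + [(p, p)] * self.nd + [(0, 0)]
        return np.pad(x, pad)

    def forward(self, x, train=False):
        self.xp = self._pad(x)
        spatial = x.shape[1:-1]
        out = np.empty(x.shape[:-1] + (self.c_out,), dtype=x.dtype)
        out[...] = self.b.value
        for o, off in enumerate(self.offsets):
            sl = (slice(None),) + tuple(slice(i, i + s) for i, s in zip(off, spatial)) \
                + (slice(None),)
            out += self.xp[sl] @ self.W.value[o]
        if not train:
            self.xp = None
        return out

    def backward(self, dout):
        spatial = dout.shape[1:-1]
        sum_axes = tuple(range(dout.ndim - 1))
        self.b.grad += dout.sum(axis=sum_axes)
        d2 = np.ascontiguousarray(dout).reshape(-1, self.c_out)
        dxp = np.zeros_like(self.xp) if self.needs_dx else None
        for o, off in enumerate(self.offsets):
            sl = (slice(None),) + tuple(slice(i, i + s) for i, s in zip(off, spatial)) \
                + (slice(None),)
            xc = np.ascontiguousarray(self.xp[sl]).reshape(-1, self.c_in)
            self.W.grad[o] += xc.T @ d2
            if dxp is not None:
                dxp[sl] += dout @ self.W.value[o].T
        if dxp is None:
            return None
        p = (self.k - 1) // 2
        if p == 0:
            return dxp
        crop = (slice(None),) + tuple(slice(p, p + s) for s in spatial) + (slice(None),)
        return dxp[crop]


class MaxPoolND(Layer):
    """2x max pooling with stride 2; gradient split evenly across ties."""

    def __init__(self, nd=3):
        self.nd = nd

    def _blocked(self, x):
        shape = [x.shape[0]]
        for s in x.shape[1:-1]:
            shape += [s // 2, 2]
        shape.append(x.shape[-1])
        return x.reshape(shape)

    def forward(self, x, train=False):
        xr = self._blocked(x)
        axes = tuple(2 + 2 * i for i in range(self.nd))
        out = xr.max(axis=axes)
        if train:
            expand = out
            for ax in axes:
                expand = np.expand_dims(expand, ax)
            mask = (xr == expand)
            self.mask = mask
            self.counts = mask.sum(axis=axes, keepdims=True)
            self.in_shape = x.shape
        return out

    def backward(self, dout):
        axes = tuple(2 + 2 * i for i in range(self.nd))
        d = dout
        for ax in axes:
            d = np.expand_dims(d, ax)
        dxr = self.mask * (d / self.counts)
        return dxr.reshape(self.in_shape).astype(dout.dtype)


class UpsampleND(Layer):
    """Nearest-neighbor 2x upsampling along every spatial axis."""

    def __init__(self, nd=3):
        self.nd = nd

    def forward(self, x, train=False):
        out = x
        for ax in range(1, 1 + self.nd):
            out = np.repeat(out, 2, axis=ax)
        return out

    def backward(self, dout):
        shape = [dout.shape[0]]
        for s in dout.shape[1:-1]:
            shape += [s // 2, 2]
        shape.append(dout.shape[-1])
        axes = tuple(2 + 2 * i for i in range(self.nd))
        return dout.reshape(shape).sum(axis=axes)


class ConvTransposeND(Layer):
    """Stride-2, kernel-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, c_in, c_out, nd=3, rng=None, dtype=np.float32):
        self.c_in, self.c_out, self.nd = c_in, c_out, nd
        n_off = 2 ** nd
        scale = np.sqrt(2.0 / c_in)
        w = rng.normal(0.0, scale, size=(c_in, n_off, c_out))
        self.W = Param(w.astype(dtype), l2=True)
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def _interleave(self, y, spatial):
        # y: (B, *spatial, n_off, D) -> (B, *2*spatial, D)
        nd = self.nd
        b = y.shape[0]
        y = y.reshape((b,) + tuple(spatial) + (2,) * nd + (self.c_out,))
        # move each factor-2 axis next to its spatial axis
        perm = [0]
        for i in range(nd):
            perm += [1 + i, 1 + nd + i]
        perm.append(1 + 2 * nd)
        y = y.transpose(perm)
        return y.reshape((b,) + tuple(2 * s for s in spatial) + (self.c_out,))

    def forward(self, x, train=False):
        if train:
            self.x = x
        spatial = x.shape[1:-1]
        y = np.tensordot(x, self.W.value, axes=([x.ndim - 1], [0]))
        out = self._interleave(y, spatial) + self.b.value
        return out.astype(x.dtype)

    def backward(self, dout):
        nd = self.nd
        spatial = self.x.shape[1:-1]
        b = dout.shape[0]
        d = dout.reshape((b,) + sum(((s, 2) for s in spatial), ()) + (self.c_out,))
        perm = [0] + [1 + 2 * i for i in range(nd)] + [2 + 2 * i for i in range(nd)] \
            + [1 + 2 * nd]
        d = d.transpose(perm).reshape((b,) + tuple(spatial) + (2 ** nd, self.c_out))
        sum_axes = tuple(range(1 + nd))
        self.b.grad += dout.sum(axis=tuple(range(dout.ndim - 1)))
        self.W.grad += np.tensordot(self.x, d, axes=(sum_axes, sum_axes))
        dx = np.tensordot(d, self.W.value, axes=([1 + nd, 2 + nd], [1, 2]))
        return dx.astype(dout.dtype)


class BatchNorm(Layer):
    """Per-channel batch normalization (channels-last)."""

    def __init__(self, c, momentum=0.9, eps=1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self.inv_sd = 1.0 / np.sqrt(var + self.eps)
            self.xhat = (x - mu) * self.inv_sd
            return (self.gamma.value * self.xhat + self.beta.value).astype(x.dtype)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean) * inv
        return (self.gamma.value * xhat + self.beta.value).astype(x.dtype)

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        n = dout.size // dout.shape[-1]
        self.gamma.grad += (dout * self.xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        dx = (self.inv_sd / n) * (
            n * dxhat - dxhat.sum(axis=axes) - self.xhat * (dxhat * self.xhat).sum(axis=axes)
        )
        return dx.astype(dout.dtype)


class Dense(Layer):
    def __init__(self, f_in, f_out, rng=None, dtype=np.float32):
        scale = np.sqrt(2.0 / f_in)
        self.W = Param(rng.normal(0.0, scale, size=(f_in, f_out)).astype(dtype), l2=True)
        self.b = Param(np.zeros(f_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        if train:
            self.x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self.x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class ELU(Layer):
    def forward(self, x, train=False):
        out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        if train:
            self.out = out
            self.pos = x > 0
        return out.astype(x.dtype)

    def backward(self, dout):
        return (dout * np.where(self.pos, 1.0, self.out + 1.0)).astype(dout.dtype)


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self.pos = x > 0
        return np.maximum(x, 0.0).astype(x.dtype)

    def backward(self, dout):
        return (dout * self.pos).astype(dout.dtype)


class Flatten(Layer):
    def forward(self, x, train=False):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.shape)


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def bce_loss_grad(logits, targets):
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps))
    grad = (p - targets) / targets.size
    return float(loss), grad.astype(logits.dtype), p


def soft_dice_loss_grad(logits, targets, smooth=1.0):
    """1 - soft Dice on sigmoid probabilities, per batch, with gradient."""
    p = sigmoid(logits)
    inter = float((p * targets).sum())
    sums = float(p.sum() + targets.sum())
    dice = (2.0 * inter + smooth) / (sums + smooth)
    # d(dice)/dp = (2*t*(sums+smooth) - (2*inter+smooth)) / (sums+smooth)^2
    dp = (2.0 * targets * (sums + smooth) - (2.0 * inter + smooth)) / (sums + smooth) ** 2
    grad = (-dp) * p * (1.0 - p)
    return float(1.0 - dice), grad.astype(logits.dtype), p


def softmax_ce_loss_grad(logits, y_index, n_classes):
    """Mean categorical cross-entropy and gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    b = logits.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(b), y_index] + eps)))
    onehot = np.zeros_like(p)
    onehot[np.arange(b), y_index] = 1.0
    grad = ((p - onehot) / b).astype(logits.dtype)
    return loss, grad, p


class Adam:
    """Adam with an L2 penalty (coefficient on the sum of squared weights)
    applied to the gradients of the flagged parameters."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, l2=0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            if p.l2 and self.l2:
                g = g + 2.0 * self.l2 * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(
                p.value.dtype)


def collect_params(layers):
    out = []
    for layer in layers:
        out.extend(layer.params())
    return out


def n_parameters(layers) -> int:
    return int(sum(p.value.size for p in collect_params(layers)))
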