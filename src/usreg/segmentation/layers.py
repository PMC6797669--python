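"""Minimal numpy neural-network layers with manual backpropagation.

Only what a compact 3D U-Net needs: same-padding 3^3 convolutions, 1^3
convolutions, batch normalization, ReLU, dropout, 2^3 max pooling and 2^3
stride-2 transposed convolutions, plus Adam.  Arrays are (N, C, D, H, W);
float32 in production, but every layer is dtype-agnostic so tests can
gradient-check in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3",
    "Conv1",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "MaxPool2",
    "UpConv2",
    "Adam",
    "bce_with_logits",
    "soft_dice_loss",
    "sigmoid",
]


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    def params(self):
        return []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


_OFFSETS = [(a, b, c) for a in range(3) for b in range(3) for c in range(3)]


class Conv3(Layer):
    """3x3x3 convolution, zero same-padding, implemented as 27 shifted GEMMs."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / (c_in * 27))
        self.W = Param((rng.standard_normal((c_out, c_in, 3, 3, 3)) * scale).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        N, C, D, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        self._xp_shape = xp.shape
        self._x_slices = []
        co = self.W.value.shape[0]
        y = np.zeros((N, co, D, H, W), dtype=x.dtype)
        yf = y.reshape(N, co, -1)
        for a, b, c in _OFFSETS:
            xs = xp[:, :, a : a + D, b : b + H, c : c + W].reshape(N, C, -1)
            self._x_slices.append(xs)
            Wo = self.W.value[:, :, a, b, c]  # (co, ci)
            yf += np.einsum("oc,ncm->nom", Wo, xs, optimize=True)
        y += self.b.value[None, :, None, None, None]
        self._in_shape = x.shape
        return y

    def backward(self, dy):
        N, co, D, H, W = dy.shape
        dyf = dy.reshape(N, co, -1)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        dxp = np.zeros(self._xp_shape, dtype=dy.dtype)
        for (a, b, c), xs in zip(_OFFSETS, self._x_slices):
            Wo = self.W.value[:, :, a, b, c]
            self.W.grad[:, :, a, b, c] += np.einsum("nom,ncm->oc", dyf, xs, optimize=True)
            dxs = np.einsum("oc,nom->ncm", Wo, dyf, optimize=True)
            dxp[:, :, a : a + D, b : b + H, c : c + W] += dxs.reshape(N, -1, D, H, W)
        self._x_slices = None
        return dxp[:, :, 1:-1, 1:-1, 1:-1]


class Conv1(Layer):
    """1x1x1 convolution (channel mixing)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / c_in)
        self.W = Param((rng.standard_normal((c_out, c_in)) * scale).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        y = np.einsum("oc,ncdhw->nodhw", self.W.value, x, optimize=True)
        return y + self.b.value[None, :, None, None, None]

    def backward(self, dy):
        self.W.grad += np.einsum("nodhw,ncdhw->oc", dy, self._x, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        dx = np.einsum("oc,nodhw->ncdhw", self.W.value, dy, optimize=True)
        self._x = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.gamma.value[None, :, None, None, None] * xhat + self.beta.value[None, :, None, None, None]

    def backward(self, dy):
        xhat, inv, training, shape = self._cache
        axes = (0, 2, 3, 4)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value[None, :, None, None, None]
        if not training:
            return dy * g * inv[None, :, None, None, None]
        m = shape[0] * shape[2] * shape[3] * shape[4]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv[None, :, None, None, None]
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2x2 max pooling; input spatial dims must be even."""

    def forward(self, x, training=False):
        N, C, D, H, W = x.shape
        xr = x.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
        blocks = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(N, C, D // 2, H // 2, W // 2, 8)
        self._arg = blocks.argmax(axis=-1)
        self._in_shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, dy):
        N, C, D, H, W = self._in_shape
        onehot = np.eye(8, dtype=dy.dtype)[self._arg]  # (..., 8)
        dblocks = dy[..., None] * onehot
        dx = (
            dblocks.reshape(N, C, D // 2, H // 2, W // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(N, C, D, H, W)
        )
        self._arg = None
        return dx


class UpConv2(Layer):
    """Transposed convolution, kernel 2^3, stride 2 (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / c_in)
        self.W = Param((rng.standard_normal((c_in, c_out, 2, 2, 2)) * scale).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        N, C, d, h, w = x.shape
        co = self.W.value.shape[1]
        t = np.tensordot(x, self.W.value, axes=([1], [0]))  # (N, d, h, w, co, 2, 2, 2)
        y = t.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(N, co, 2 * d, 2 * h, 2 * w)
        return y + self.b.value[None, :, None, None, None]

    def backward(self, dy):
        x = self._x
        N, C, d, h, w = x.shape
        co = self.W.value.shape[1]
        dt = dy.reshape(N, co, d, 2, h, 2, w, 2).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        self.W.grad += np.tensordot(x, dt, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
        dx = np.tensordot(dt, self.W.value, axes=([4, 5, 6, 7], [1, 2, 3, 4])).transpose(0, 4, 1, 2, 3)
        self._x = None
        return dx


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy; returns (loss, dloss/dlogits)."""
    z, y = logits, targets
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    return float(loss.mean()), (sigmoid(z) - y) / n


def soft_dice_loss(logits, targets, eps=1.0):
    """1 - soft Dice; returns (loss, dloss/dlogits)."""
    p = sigmoid(logits)
    y = targets
    num = 2.0 * float((p * y).sum()) + eps
    den = float(p.sum() + y.sum()) + eps
    loss = 1.0 - num / den
    dnum_dp = 2.0 * y
    dloss_dp = -(dnum_dp * den - num) / den**2
    return float(loss), dloss_dp * p * (1.0 - p)
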