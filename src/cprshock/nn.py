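"""Minimal NumPy building blocks for the 1-D fully convolutional classifier.

Implements exactly the pieces the shock-advisory network needs — 1-D
convolution with "same" padding, ReLU, max-pooling, inverted dropout,
global average pooling, a dense head, the class-weighted binary
cross-entropy and Adam — with explicit forward/backward passes in
float32. Convolutions are lowered to a single GEMM per layer via an
im2col view, which keeps training of the 27k-parameter model practical
on one CPU core.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "Dropout",
    "GlobalAveragePooling1D",
    "Dense",
    "Sequential",
    "Adam",
    "sigmoid",
    "weighted_bce_from_logits",
]

_F32 = np.float32


def sigmoid(x):
    """Logistic function 1 / (1 + e^-x), numerically stable on both tails."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    trainable = False

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def params(self):
        return []

    @property
    def grads(self):
        return []


class Conv1D(Layer):
    """1-D convolution, stride 1, "same" padding; input/output (B, L, C).

    Channels-last layout keeps every im2col patch a contiguous block, so
    both the forward pass and both backward products are plain GEMMs.
    """

    trainable = True

    def __init__(self, in_channels, filters, kernel_size, rng, init_scale=0.05):
        self.C, self.F, self.K = in_channels, filters, kernel_size
        # kernel as a (K*C, F) GEMM matrix; 'random uniform' initialisation
        self.W = rng.uniform(-init_scale, init_scale,
                             size=(self.K * self.C, self.F)).astype(_F32)
        self.b = np.zeros(self.F, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.pad_left = (self.K - 1) // 2
        self.pad_right = self.K - 1 - self.pad_left
        self._bufs = {}  # (slot, B, L, dtype) -> reused patch buffer

    @property
    def n_params(self):
        return self.W.size + self.b.size

    def _im2col(self, x, K, pad, slot):
        """(B, L, C) -> (B*L, K*C) patches, kernel index major.

        Patches are gathered into a reused per-layer, per-batch-shape
        buffer: each patch is one contiguous K*C block of the padded
        channels-last signal, so the gather is a memcpy per output row,
        and recurring batch shapes (training batch, trailing partial
        batch, validation chunks) never reallocate.
        """
        B, L, C = x.shape
        xp = np.pad(x, ((0, 0), pad, (0, 0)))
        flat = xp.reshape(B, -1)
        win = np.lib.stride_tricks.sliding_window_view(flat, K * C, axis=1)[:, ::C, :]
        key = (slot, B, L, x.dtype.str)
        buf = self._bufs.get(key)
        if buf is None:
            if len(self._bufs) > 8:
                self._bufs.clear()
            buf = self._bufs[key] = np.empty((B, L, K * C), dtype=x.dtype)
        np.copyto(buf, win)
        return buf.reshape(B * L, K * C)

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        cols = self._im2col(x, self.K, (self.pad_left, self.pad_right), "_fwd_buf")
        self._cols, self._shape = cols, (B, L, C)
        return (cols @ self.W + self.b).reshape(B, L, self.F)

    def backward(self, grad):
        B, L, C = self._shape
        g = grad.reshape(B * L, self.F)
        self.dW = self._cols.T @ g
        self.db = g.sum(axis=0)
        # dX is the full correlation of the output gradient with the
        # flipped kernel — one more im2col GEMM instead of a scatter-add
        Wback = (self.W.reshape(self.K, C, self.F)[::-1]
                 .transpose(0, 2, 1).reshape(self.K * self.F, C))
        gcols = self._im2col(grad, self.K, (self.pad_right, self.pad_left), "_bwd_buf")
        return (gcols @ Wback).reshape(B, L, C)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Max pooling with pool size 2; trailing odd sample is dropped."""

    def __init__(self, pool=2):
        self.pool = pool

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        Lo = L // self.pool
        xv = x[:, : Lo * self.pool, :].reshape(B, Lo, self.pool, C)
        self._arg = xv.argmax(axis=2)
        self._shape = (B, L, C)
        return np.take_along_axis(xv, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        B, L, C = self._shape
        Lo = grad.shape[1]
        dx = np.zeros((B, Lo, self.pool, C), dtype=grad.dtype)
        np.put_along_axis(dx, self._arg[:, :, None, :], grad[:, :, None, :], axis=2)
        out = np.zeros((B, L, C), dtype=grad.dtype)
        out[:, : Lo * self.pool, :] = dx.reshape(B, Lo * self.pool, C)
        return out


class Dropout(Layer):
    """Inverted dropout: identity at inference time."""

    def __init__(self, rate=0.3):
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        u = rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class GlobalAveragePooling1D(Layer):
    """(B, L, C) -> (B, C), averaging each filter's output over time."""

    def forward(self, x, train=False, rng=None):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.broadcast_to(grad[:, None, :] / self._L,
                               (grad.shape[0], self._L, grad.shape[1])).copy()


class Dense(Layer):
    """Fully connected (B, C) -> (B, units); emits logits."""

    trainable = True

    def __init__(self, in_features, units, rng, init_scale=0.05):
        self.W = rng.uniform(-init_scale, init_scale,
                             size=(in_features, units)).astype(_F32)
        self.b = np.zeros(units, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self):
        return self.W.size + self.b.size

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    @property
    def n_params(self):
        return sum(p.size for p in self.params)

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p[...] = w


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p[...] = p - lr_t * m / (np.sqrt(v) + self.eps)


def weighted_bce_from_logits(logits, targets, w_sh, w_nsh):
    """Class-weighted BCE and its gradient w.r.t. the logits.

    loss = -1/M Σ [δ·w_Sh·log p + (1-δ)·w_NSh·log(1-p)], p = σ(logit).
    The fused formulation avoids the clipped-log instability of the
    probability-space loss during training.
    """
    z = logits.ravel().astype(float)
    d = targets.ravel().astype(float)
    p = sigmoid(z)
    # log σ(z) = -log(1+e^-z), computed stably via logaddexp
    log_p = -np.logaddexp(0.0, -z)
    log_1mp = -np.logaddexp(0.0, z)
    m = len(z)
    loss = -np.mean(d * w_sh * log_p + (1 - d) * w_nsh * log_1mp)
    dz = (d * w_sh * (p - 1.0) + (1 - d) * w_nsh * p) / m
    return float(loss), dz.reshape(logits.shape)
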