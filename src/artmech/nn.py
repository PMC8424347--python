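"""Minimal numpy neural-network primitives with explicit backpropagation.

Only what the hybrid model's encoder/head needs: 2D convolution, batch
normalization with exponential-moving-average inference statistics, ReLU,
softplus, 3x3 max pooling, global average pooling, dense layers, Glorot
uniform initialization and the Adam optimizer.

Activations are laid out as (R, N, C, H, W): a batch of N images in
channels-first order, replicated across R independent "ensemble lanes".
Every lane carries its own weights (leading axis R on every parameter),
so R identically-structured networks that see the same mini-batches --
e.g. the multi-restart training protocol -- run in lockstep through
batched matrix products instead of R separate passes.  R = 1 is the
ordinary single-network case.  An input with lane axis 1 broadcasts
against R weight lanes (used by the first layer, whose im2col windows are
shared by all lanes).

Convolutions run as one im2col copy plus one batched BLAS matrix product;
the input gradient is col2im: one batched product followed by one strided
add per kernel tap, so no scatter-gather appears on the hot path.  Layers
cache what their backward pass needs during ``forward`` and return input
gradients from ``backward``.  Float32 is the training default; the
finite-difference gradient checks use float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .errors import DomainError
from . import _kernels as _K

__all__ = [
    "Param", "glorot_uniform", "Conv2D", "BatchNorm2D", "ReLU", "Softplus",
    "MaxPool2D", "GlobalAvgPool", "Dense", "Adam", "softplus",
]


def softplus(x):
    """Numerically stable log(1 + exp(x))."""
    return np.logaddexp(0.0, x)


class Param:
    """A trainable array with its gradient accumulator.

    The leading axis indexes ensemble lanes (independent weight sets)."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value, name=""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    def zero_grad(self):
        self.grad[...] = 0.0


def glorot_uniform(rngs, shape, fan_in, fan_out, dtype):
    """Stacked Glorot-uniform draws, one independent rng per lane."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return np.stack([rng.uniform(-limit, limit, size=shape).astype(dtype)
                     for rng in rngs])


def _pad_sp(x, ph, pw, value=0.0):
    """Zero- (or value-) pad the two spatial axes of (R, N, C, H, W)."""
    r, n, c, h, w = x.shape
    if value == 0.0:
        out = np.zeros((r, n, c, h + 2 * ph, w + 2 * pw), dtype=x.dtype)
    else:
        out = np.full((r, n, c, h + 2 * ph, w + 2 * pw), value, dtype=x.dtype)
    out[:, :, :, ph:ph + h, pw:pw + w] = x
    return out


class Conv2D:
    """2D convolution (cross-correlation) over (R, N, C, H, W) tensors.

    The kernel is stored flattened as (R, C*k*k, O) with taps ordered
    (channel, row, col) to match the im2col layout.
    """

    def __init__(self, in_ch, out_ch, kernel, stride, pad, rngs,
                 dtype=np.float32, name="conv", need_input_grad=True,
                 bias=True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.need_input_grad = need_input_grad
        if pad > kernel - 1:
            raise DomainError("pad > kernel-1 is not supported")
        k = kernel
        fan_in = in_ch * k * k
        fan_out = out_ch * k * k
        self.W = Param(glorot_uniform(rngs, (in_ch * k * k, out_ch),
                                      fan_in, fan_out, dtype), name + ".W")
        # a convolution straight into batch norm needs no bias
        self.b = Param(np.zeros((len(rngs), 1, out_ch), dtype=dtype),
                       name + ".b") if bias else None
        self.name = name

    @property
    def params(self):
        return [self.W, self.b] if self.b is not None else [self.W]

    def out_shape(self, h, w):
        k, s, p = self.kernel, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def im2col(self, x):
        """(R, N*OH*OW, C*k*k) contiguous im2col matrix.  Constant for
        fixed inputs, so callers may precompute it once and replay it via
        :meth:`forward_cols`."""
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = _pad_sp(x, p, p)
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(3, 4))
        win = win[:, :, :, ::s, ::s]  # (R, N, C, OH, OW, k, k)
        r, n, c, oh, ow = win.shape[:5]
        cols = win.transpose(0, 1, 3, 4, 2, 5, 6).reshape(r, n * oh * ow, -1)
        return cols, n, oh, ow

    def forward(self, x, training=False):
        self._in_hw = x.shape[3:5]
        if (_K.HAVE_NUMBA and self.kernel == 3 and self.in_ch <= 4
                and x.shape[0] == self.W.value.shape[0]):
            # direct unrolled 3x3 convolution (faster than im2col at the
            # residual blocks' channel counts); caches the padded input
            s, p = self.stride, self.pad
            xp = _pad_sp(x, p, p) if p else x
            self._xp = xp
            self._cols = None
            r, n = x.shape[:2]
            oh, ow = self.out_shape(*self._in_hw)
            y = np.zeros((r, n, self.out_ch, oh, ow), dtype=x.dtype)
            _K.conv3_fwd(xp, self.W.value, y, s)
            if self.b is not None:
                y += self.b.value.reshape(r, 1, self.out_ch, 1, 1)
            return y
        cols, n, oh, ow = self.im2col(x)
        return self.forward_cols(cols, n, oh, ow)

    def forward_cols(self, cols, n, oh, ow):
        self._cols = cols
        self._xp = None
        R = self.W.value.shape[0]
        if cols.shape[0] == 1 and R > 1:
            # lane-shared input: one wide product instead of a slow
            # broadcast loop, lanes merged into the output columns
            Wm = self.W.value.transpose(1, 0, 2).reshape(self.W.value.shape[1], -1)
            y = (cols[0] @ Wm).reshape(-1, R, self.out_ch)
            y = y.transpose(1, 0, 2)
        else:
            y = np.matmul(cols, self.W.value)  # (R, N*OH*OW, O)
        if self.b is not None:
            y = y + self.b.value
        y = y.reshape(-1, n, oh, ow, self.out_ch)
        return np.ascontiguousarray(y.transpose(0, 1, 4, 2, 3))

    def backward(self, dy):
        k, s, p = self.kernel, self.stride, self.pad
        r, n, _, oh, ow = dy.shape
        if self._cols is None:
            # direct path
            dy = np.ascontiguousarray(dy)
            _K.conv3_dw(self._xp, dy, self.W.grad, s)
            if self.b is not None:
                self.b.grad += dy.sum(axis=(1, 3, 4)).reshape(r, 1, -1)
            if not self.need_input_grad:
                return None
            h, w = self._in_hw
            dxp = np.zeros((r, n, self.in_ch, h + 2 * p, w + 2 * p),
                           dtype=dy.dtype)
            _K.conv3_dx(dy, self.W.value, dxp, s)
            return dxp[:, :, :, p:p + h, p:p + w] if p else dxp
        dy2 = np.ascontiguousarray(dy.transpose(0, 1, 3, 4, 2)).reshape(
            r, -1, self.out_ch)
        cols = self._cols
        if cols.shape[0] == 1 and r > 1:
            # lane-shared input: merge lanes into columns for one product
            dm = np.ascontiguousarray(dy2.transpose(1, 0, 2)).reshape(
                dy2.shape[1], -1)
            gW = (cols[0].T @ dm).reshape(-1, r, self.out_ch)
            self.W.grad += gW.transpose(1, 0, 2)
        else:
            self.W.grad += np.matmul(cols.transpose(0, 2, 1), dy2)
        if self.b is not None:
            self.b.grad += dy2.sum(axis=1, keepdims=True)
        if not self.need_input_grad:
            return None
        h, w = self._in_hw
        if s == 1:
            # transposed convolution as windows + one batched product with
            # the flipped kernel (in/out channels swapped)
            q = k - 1 - p
            if q or (oh != h) or (ow != w):
                dyp = np.zeros((r, n, self.out_ch, h + k - 1, w + k - 1),
                               dtype=dy.dtype)
                dyp[:, :, :, q:q + oh, q:q + ow] = dy
            else:
                dyp = dy
            Wb = self.W.value.reshape(r, self.in_ch, k, k, self.out_ch)
            Wb = Wb[:, :, ::-1, ::-1, :].transpose(0, 4, 2, 3, 1)
            Wb = np.ascontiguousarray(Wb).reshape(r, -1, self.in_ch)
            zwin = np.lib.stride_tricks.sliding_window_view(
                dyp, (k, k), axis=(3, 4))
            zcols = zwin.transpose(0, 1, 3, 4, 2, 5, 6).reshape(r, n * h * w, -1)
            dx = np.matmul(zcols, Wb).reshape(r, n, h, w, self.in_ch)
            return np.ascontiguousarray(dx.transpose(0, 1, 4, 2, 3))
        # strided case: col2im, one batched product then one strided add
        # per kernel tap
        g = np.matmul(dy2, self.W.value.transpose(0, 2, 1))
        g = g.reshape(r, n, oh, ow, self.in_ch, k, k).transpose(
            0, 1, 4, 2, 3, 5, 6)
        dxp = np.zeros((r, n, self.in_ch, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        eh = (oh - 1) * s + 1
        ew = (ow - 1) * s + 1
        for u in range(k):
            for v in range(k):
                dxp[:, :, :, u:u + eh:s, v:v + ew:s] += g[..., u, v]
        return dxp[:, :, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2D:
    """Per-channel, per-lane batch normalization for (R, N, C, H, W).
    Inference uses exponential-moving-average statistics."""

    def __init__(self, channels, n_lanes=1, momentum=0.99, eps=1e-5,
                 dtype=np.float32, name="bn"):
        shape = (n_lanes, 1, channels, 1, 1)
        self.gamma = Param(np.ones(shape, dtype=dtype), name + ".gamma")
        self.beta = Param(np.zeros(shape, dtype=dtype), name + ".beta")
        self.running_mean = np.zeros(shape, dtype=dtype)
        self.running_var = np.ones(shape, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.name = name

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if _K.HAVE_NUMBA:
            return self._forward_fused(x, training)
        axes = (1, 3, 4)
        if training:
            mean = x.mean(axis=axes, keepdims=True)
            xc = x - mean
            m = x.shape[1] * x.shape[3] * x.shape[4]
            var = np.einsum("rnchw,rnchw->rc", xc, xc).reshape(mean.shape) / m
            mom = self.momentum
            self.running_mean = (mom * self.running_mean + (1 - mom) * mean
                                 ).astype(self.running_mean.dtype)
            self.running_var = (mom * self.running_var + (1 - mom) * var
                                ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
            xc = x - mean
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = xc * inv
        self._cache = (xhat, inv, training)
        return self.gamma.value * xhat + self.beta.value

    def _forward_fused(self, x, training):
        r, n, c, h, w = x.shape
        shape5 = self.gamma.value.shape
        if training:
            mean = np.empty((r, c), dtype=x.dtype)
            var = np.empty((r, c), dtype=x.dtype)
            _K.bn_stats(np.ascontiguousarray(x), mean, var)
            mom = self.momentum
            self.running_mean = (mom * self.running_mean
                                 + (1 - mom) * mean.reshape(shape5)).astype(
                self.running_mean.dtype)
            self.running_var = (mom * self.running_var
                                + (1 - mom) * var.reshape(shape5)).astype(
                self.running_var.dtype)
        else:
            mean = self.running_mean.reshape(r, c).astype(x.dtype)
            var = self.running_var.reshape(r, c).astype(x.dtype)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = np.empty_like(x)
        out = np.empty_like(x)
        _K.bn_apply(np.ascontiguousarray(x), np.ascontiguousarray(mean), inv,
                    self.gamma.value.reshape(r, c).astype(x.dtype),
                    self.beta.value.reshape(r, c).astype(x.dtype), xhat, out)
        self._cache = (xhat, inv, training)
        return out

    def backward(self, dy):
        xhat, inv, training = self._cache
        if _K.HAVE_NUMBA:
            r, c = xhat.shape[0], xhat.shape[2]
            inv2 = np.ascontiguousarray(inv).reshape(r, c)
            dg = self.gamma.grad.reshape(r, c)
            db = self.beta.grad.reshape(r, c)
            dx = np.empty_like(xhat)
            _K.bn_bwd(np.ascontiguousarray(dy), xhat, inv2,
                      self.gamma.value.reshape(r, c), dg, db, dx, training)
            return dx
        axes = (1, 3, 4)
        self.gamma.grad += np.einsum("rnchw,rnchw->rc", dy, xhat).reshape(
            self.gamma.value.shape)
        self.beta.grad += dy.sum(axis=axes, keepdims=True)
        g = self.gamma.value
        if not training:
            return dy * (g * inv)
        m = dy.shape[1] * dy.shape[3] * dy.shape[4]
        dxhat = dy * g
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = np.einsum("rnchw,rnchw->rc", dxhat, xhat).reshape(s1.shape)
        return (inv / m) * (m * dxhat - s1 - xhat * s2)


class ReLU:
    params = ()

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Softplus:
    params = ()

    def forward(self, x, training=False):
        self._x = x
        return softplus(x)

    def backward(self, dy):
        return dy * expit(self._x)


class MaxPool2D:
    """Max pooling over the spatial axes with -inf padding."""

    params = ()

    def __init__(self, kernel=3, stride=2, pad=1):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x, training=False):
        k, s, p = self.kernel, self.stride, self.pad
        r, n, c, h, w = x.shape
        xp = _pad_sp(x, p, p, value=-np.inf) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        eh = (oh - 1) * s + 1
        ew = (ow - 1) * s + 1
        # separable max: over rows first, then columns
        rows = np.full((r, n, c, oh, xp.shape[4]), -np.inf, dtype=x.dtype)
        for u in range(k):
            np.maximum(rows, xp[:, :, :, u:u + eh:s], out=rows)
        y = np.full((r, n, c, oh, ow), -np.inf, dtype=x.dtype)
        for v in range(k):
            np.maximum(y, rows[:, :, :, :, v:v + ew:s], out=y)
        self._cache = (xp, y, (h, w), (eh, ew))
        return y

    def backward(self, dy):
        # route each window's gradient to the first tap attaining the max
        k, s, p = self.kernel, self.stride, self.pad
        xp, y, (h, w), (eh, ew) = self._cache
        dxp = np.zeros(xp.shape, dtype=dy.dtype)
        if _K.HAVE_NUMBA:
            _K.pool_bwd(xp, y, np.ascontiguousarray(dy), dxp, k, s)
            return dxp[:, :, :, p:p + h, p:p + w]
        alive = np.ones(dy.shape, dtype=bool)
        for u in range(k):
            for v in range(k):
                hit = alive & (xp[:, :, :, u:u + eh:s, v:v + ew:s] == y)
                dxp[:, :, :, u:u + eh:s, v:v + ew:s] += dy * hit
                alive &= ~hit
        return dxp[:, :, :, p:p + h, p:p + w]


class GlobalAvgPool:
    params = ()

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(3, 4))

    def backward(self, dy):
        r, n, c, h, w = self._shape
        # read-only broadcast view; the consumer never writes in place
        return np.broadcast_to(dy[:, :, :, None, None] / (h * w), self._shape)


class Dense:
    """Per-lane affine map over (R, N, F) tensors."""

    def __init__(self, n_in, n_out, rngs, dtype=np.float32, name="dense"):
        self.W = Param(glorot_uniform(rngs, (n_in, n_out), n_in, n_out, dtype),
                       name + ".W")
        self.b = Param(np.zeros((len(rngs), 1, n_out), dtype=dtype),
                       name + ".b")
        self.name = name

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return np.matmul(x, self.W.value) + self.b.value

    def backward(self, dy):
        self.W.grad += np.matmul(self._x.transpose(0, 2, 1), dy)
        self.b.grad += dy.sum(axis=1, keepdims=True)
        return np.matmul(dy, self.W.value.transpose(0, 2, 1))


class Adam:
    """Adam optimizer (Keras-style defaults: eps = 1e-7)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        if not self.params:
            raise DomainError("Adam needs at least one parameter")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
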