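"""JIT-compiled kernels for the hot layers of the encoder.

The encoder's early convolutions have 1-4 channels on comparatively large
feature maps; im2col there is dominated by window copies rather than
arithmetic, so a direct 3x3 convolution with unrolled taps is faster.
Deeper blocks (8-16 channels, tiny feature maps) stay on the im2col /
BLAS path.  Batch normalization and max pooling are fused single-pass
kernels over the channels-first (R, N, C, H, W) layout.

The flattened weight layout matches :class:`artmech.nn.Conv2D`:
``W[r, (c*k + u)*k + v, o]`` is the tap (row u, col v) connecting input
channel c to output channel o of lane r.

When numba is unavailable the callers fall back to pure numpy paths.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco


# ---------------------------------------------------------------------------
# direct 3x3 convolution (k fixed so the tap loops unroll)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def conv3_fwd(xp, W, y, s):
    """3x3 convolution on the padded input; y must be zero-initialized."""
    R, N, C, Hp, Wp = xp.shape
    O = y.shape[2]
    OH = y.shape[3]
    OW = y.shape[4]
    for r in range(R):
        for n in range(N):
            for o in range(O):
                yimg = y[r, n, o]
                for c in range(C):
                    ximg = xp[r, n, c]
                    w00 = W[r, (c * 3 + 0) * 3 + 0, o]
                    w01 = W[r, (c * 3 + 0) * 3 + 1, o]
                    w02 = W[r, (c * 3 + 0) * 3 + 2, o]
                    w10 = W[r, (c * 3 + 1) * 3 + 0, o]
                    w11 = W[r, (c * 3 + 1) * 3 + 1, o]
                    w12 = W[r, (c * 3 + 1) * 3 + 2, o]
                    w20 = W[r, (c * 3 + 2) * 3 + 0, o]
                    w21 = W[r, (c * 3 + 2) * 3 + 1, o]
                    w22 = W[r, (c * 3 + 2) * 3 + 2, o]
                    for i in range(OH):
                        ii = i * s
                        x0 = ximg[ii]
                        x1 = ximg[ii + 1]
                        x2 = ximg[ii + 2]
                        yrow = yimg[i]
                        for j in range(OW):
                            jj = j * s
                            yrow[j] += (x0[jj] * w00 + x0[jj + 1] * w01
                                        + x0[jj + 2] * w02
                                        + x1[jj] * w10 + x1[jj + 1] * w11
                                        + x1[jj + 2] * w12
                                        + x2[jj] * w20 + x2[jj + 1] * w21
                                        + x2[jj + 2] * w22)


@njit(cache=True, fastmath=True)
def conv3_dw(xp, dy, dW, s):
    """Weight gradient of the 3x3 convolution."""
    R, N, C, Hp, Wp = xp.shape
    O = dy.shape[2]
    OH = dy.shape[3]
    OW = dy.shape[4]
    for r in range(R):
        for o in range(O):
            for c in range(C):
                a00 = a01 = a02 = a10 = a11 = a12 = a20 = a21 = a22 = \
                    xp[0, 0, 0, 0, 0] * 0.0
                for n in range(N):
                    dimg = dy[r, n, o]
                    ximg = xp[r, n, c]
                    for i in range(OH):
                        ii = i * s
                        drow = dimg[i]
                        x0 = ximg[ii]
                        x1 = ximg[ii + 1]
                        x2 = ximg[ii + 2]
                        for j in range(OW):
                            d = drow[j]
                            jj = j * s
                            a00 += x0[jj] * d
                            a01 += x0[jj + 1] * d
                            a02 += x0[jj + 2] * d
                            a10 += x1[jj] * d
                            a11 += x1[jj + 1] * d
                            a12 += x1[jj + 2] * d
                            a20 += x2[jj] * d
                            a21 += x2[jj + 1] * d
                            a22 += x2[jj + 2] * d
                base = c * 9
                dW[r, base + 0, o] += a00
                dW[r, base + 1, o] += a01
                dW[r, base + 2, o] += a02
                dW[r, base + 3, o] += a10
                dW[r, base + 4, o] += a11
                dW[r, base + 5, o] += a12
                dW[r, base + 6, o] += a20
                dW[r, base + 7, o] += a21
                dW[r, base + 8, o] += a22


@njit(cache=True, fastmath=True)
def conv3_dx(dy, W, dxp, s):
    """Input gradient of the 3x3 convolution (into the padded buffer,
    zero-initialized)."""
    R, N, O, OH, OW = dy.shape
    C = dxp.shape[2]
    for r in range(R):
        for n in range(N):
            for c in range(C):
                dximg = dxp[r, n, c]
                for o in range(O):
                    dimg = dy[r, n, o]
                    w00 = W[r, c * 9 + 0, o]
                    w01 = W[r, c * 9 + 1, o]
                    w02 = W[r, c * 9 + 2, o]
                    w10 = W[r, c * 9 + 3, o]
                    w11 = W[r, c * 9 + 4, o]
                    w12 = W[r, c * 9 + 5, o]
                    w20 = W[r, c * 9 + 6, o]
                    w21 = W[r, c * 9 + 7, o]
                    w22 = W[r, c * 9 + 8, o]
                    for i in range(OH):
                        ii = i * s
                        drow = dimg[i]
                        x0 = dximg[ii]
                        x1 = dximg[ii + 1]
                        x2 = dximg[ii + 2]
                        for j in range(OW):
                            d = drow[j]
                            jj = j * s
                            x0[jj] += d * w00
                            x0[jj + 1] += d * w01
                            x0[jj + 2] += d * w02
                            x1[jj] += d * w10
                            x1[jj + 1] += d * w11
                            x1[jj + 2] += d * w12
                            x2[jj] += d * w20
                            x2[jj + 1] += d * w21
                            x2[jj + 2] += d * w22


# ---------------------------------------------------------------------------
# fused batch normalization (+ cached xhat) on (R, N, C, H, W)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def bn_stats(x, mean, var):
    """Per-(lane, channel) mean and population variance."""
    R, N, C, H, W = x.shape
    m = N * H * W
    for r in range(R):
        for c in range(C):
            s = x[0, 0, 0, 0, 0] * 0.0
            for n in range(N):
                img = x[r, n, c]
                for i in range(H):
                    row = img[i]
                    for j in range(W):
                        s += row[j]
            mu = s / m
            q = s * 0.0
            for n in range(N):
                img = x[r, n, c]
                for i in range(H):
                    row = img[i]
                    for j in range(W):
                        d = row[j] - mu
                        q += d * d
            mean[r, c] = mu
            var[r, c] = q / m


@njit(cache=True, fastmath=True)
def bn_apply(x, mean, inv, gamma, beta, xhat, out):
    """xhat = (x - mean) * inv; out = gamma * xhat + beta (one pass)."""
    R, N, C, H, W = x.shape
    for r in range(R):
        for c in range(C):
            mu = mean[r, c]
            iv = inv[r, c]
            g = gamma[r, c]
            b = beta[r, c]
            for n in range(N):
                ximg = x[r, n, c]
                himg = xhat[r, n, c]
                oimg = out[r, n, c]
                for i in range(H):
                    xrow = ximg[i]
                    hrow = himg[i]
                    orow = oimg[i]
                    for j in range(W):
                        h = (xrow[j] - mu) * iv
                        hrow[j] = h
                        orow[j] = g * h + b


@njit(cache=True, fastmath=True)
def bn_bwd(dy, xhat, inv, gamma, dgamma, dbeta, dx, training):
    """Batch-norm backward; also accumulates dgamma/dbeta.  In training
    mode the batch-statistics terms are included."""
    R, N, C, H, W = dy.shape
    m = N * H * W
    for r in range(R):
        for c in range(C):
            s1 = dy[0, 0, 0, 0, 0] * 0.0
            s2 = s1
            for n in range(N):
                dimg = dy[r, n, c]
                himg = xhat[r, n, c]
                for i in range(H):
                    drow = dimg[i]
                    hrow = himg[i]
                    for j in range(W):
                        s1 += drow[j]
                        s2 += drow[j] * hrow[j]
            dgamma[r, c] += s2
            dbeta[r, c] += s1
            g = gamma[r, c]
            iv = inv[r, c]
            if training:
                k1 = g * iv
                a1 = s1 / m
                a2 = s2 / m
                for n in range(N):
                    dimg = dy[r, n, c]
                    himg = xhat[r, n, c]
                    oimg = dx[r, n, c]
                    for i in range(H):
                        drow = dimg[i]
                        hrow = himg[i]
                        orow = oimg[i]
                        for j in range(W):
                            orow[j] = k1 * (drow[j] - a1 - hrow[j] * a2)
            else:
                k1 = g * iv
                for n in range(N):
                    dimg = dy[r, n, c]
                    oimg = dx[r, n, c]
                    for i in range(H):
                        drow = dimg[i]
                        orow = oimg[i]
                        for j in range(W):
                            orow[j] = k1 * drow[j]


# ---------------------------------------------------------------------------
# max-pool backward (first-tap tie routing, matching the forward max)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def pool_bwd(xp, y, dy, dxp, k, s):
    """Route each pooled window's gradient to the first tap attaining the
    window maximum; dxp (padded input shape) must be zero-initialized."""
    R, N, C, OH, OW = dy.shape
    for r in range(R):
        for n in range(N):
            for c in range(C):
                ximg = xp[r, n, c]
                yimg = y[r, n, c]
                dimg = dy[r, n, c]
                oimg = dxp[r, n, c]
                for i in range(OH):
                    ii = i * s
                    for j in range(OW):
                        jj = j * s
                        m = yimg[i, j]
                        done = False
                        for u in range(k):
                            if done:
                                break
                            for v in range(k):
                                if ximg[ii + u, jj + v] == m:
                                    oimg[ii + u, jj + v] += dimg[i, j]
                                    done = True
                                    break
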