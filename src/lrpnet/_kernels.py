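"""Numba-compiled kernels for the memory-bound layers.

The depthwise 3x3 convolution and the same-padded average pooling are
bandwidth-limited when expressed as shifted numpy slice arithmetic (each
tap re-reads the whole feature map).  These single-pass loops are the
same arithmetic fused into one traversal; `lrpnet.nn` falls back to the
numpy formulation when numba is unavailable.
"""

from __future__ import annotations

from numba import njit

__all__ = [
    "dw3x3_forward", "dw3x3_backward", "avgpool_forward", "avgpool_backward",
    "bn_forward", "bn_reduce", "bn_backward_dx", "relu_backward",
    "mul_gate", "dot_hw", "gate_backward_dx",
]


@njit(cache=True, fastmath=True)
def bn_forward(x, mean, inv, gamma, beta, y):
    n, c, h, w = x.shape
    for b in range(n):
        for ch in range(c):
            a = gamma[ch] * inv[ch]
            o = beta[ch] - a * mean[ch]
            for i in range(h):
                for j in range(w):
                    y[b, ch, i, j] = a * x[b, ch, i, j] + o


@njit(cache=True, fastmath=True)
def bn_reduce(x, dy, mean, inv, sum_dy, sum_dy_xhat):
    n, c, h, w = x.shape
    for b in range(n):
        for ch in range(c):
            s0 = 0.0
            s1 = 0.0
            for i in range(h):
                for j in range(w):
                    d = dy[b, ch, i, j]
                    s0 += d
                    s1 += d * (x[b, ch, i, j] - mean[ch]) * inv[ch]
            sum_dy[ch] += s0
            sum_dy_xhat[ch] += s1


@njit(cache=True, fastmath=True)
def bn_backward_dx(x, dy, mean, inv, gamma, sum_dy, sum_dy_xhat, m, train, dx):
    n, c, h, w = x.shape
    for b in range(n):
        for ch in range(c):
            g = gamma[ch] * inv[ch]
            c0 = sum_dy[ch] / m
            c1 = sum_dy_xhat[ch] / m
            for i in range(h):
                for j in range(w):
                    if train:
                        xhat = (x[b, ch, i, j] - mean[ch]) * inv[ch]
                        dx[b, ch, i, j] = g * (dy[b, ch, i, j] - c0 - xhat * c1)
                    else:
                        dx[b, ch, i, j] = g * dy[b, ch, i, j]


@njit(cache=True, fastmath=True)
def relu_backward(dy, y, dx):
    f = dy.reshape(-1)
    o = y.reshape(-1)
    d = dx.reshape(-1)
    for i in range(f.size):
        d[i] = f[i] if o[i] > 0.0 else 0.0


@njit(cache=True, fastmath=True)
def mul_gate(x, g, y):
    n, c, h, w = x.shape
    for b in range(n):
        for ch in range(c):
            gv = g[b, ch]
            for i in range(h):
                for j in range(w):
                    y[b, ch, i, j] = gv * x[b, ch, i, j]


@njit(cache=True, fastmath=True)
def dot_hw(a, b, out):
    n, c, h, w = a.shape
    for bb in range(n):
        for ch in range(c):
            s = 0.0
            for i in range(h):
                for j in range(w):
                    s += a[bb, ch, i, j] * b[bb, ch, i, j]
            out[bb, ch] = s


@njit(cache=True, fastmath=True)
def gate_backward_dx(dy, x, g, ds_scaled, dx):
    n, c, h, w = dy.shape
    for b in range(n):
        for ch in range(c):
            gv = g[b, ch]
            add = ds_scaled[b, ch]
            for i in range(h):
                for j in range(w):
                    dx[b, ch, i, j] = gv * dy[b, ch, i, j] + add


@njit(cache=True, fastmath=True)
def dw3x3_forward(x, w, y):
    n, c, h, ww = x.shape
    for b in range(n):
        for ch in range(c):
            k = w[ch]
            for i in range(h):
                for j in range(ww):
                    acc = 0.0
                    for di in range(-1, 2):
                        ii = i + di
                        if ii < 0 or ii >= h:
                            continue
                        for dj in range(-1, 2):
                            jj = j + dj
                            if jj < 0 or jj >= ww:
                                continue
                            acc += k[di + 1, dj + 1] * x[b, ch, ii, jj]
                    y[b, ch, i, j] = acc


@njit(cache=True, fastmath=True)
def dw3x3_backward(x, w, dy, dw, dx):
    n, c, h, ww = x.shape
    for b in range(n):
        for ch in range(c):
            k = w[ch]
            for i in range(h):
                for j in range(ww):
                    g = dy[b, ch, i, j]
                    acc = 0.0
                    for di in range(-1, 2):
                        ii = i + di
                        if ii < 0 or ii >= h:
                            continue
                        for dj in range(-1, 2):
                            jj = j + dj
                            if jj < 0 or jj >= ww:
                                continue
                            # dL/dw accumulates x * dy over valid taps;
                            # dx is the correlation of dy with the
                            # flipped kernel, folded into the same pass.
                            dw[ch, di + 1, dj + 1] += x[b, ch, ii, jj] * g
                            acc += k[1 - di, 1 - dj] * dy[b, ch, ii, jj]
                    dx[b, ch, i, j] = acc


@njit(cache=True, fastmath=True)
def avgpool_forward(x, k, y):
    n, c, h, ww = x.shape
    p = k // 2
    for b in range(n):
        for ch in range(c):
            for i in range(h):
                i0 = max(0, i - p)
                i1 = min(h, i + p + 1)
                for j in range(ww):
                    j0 = max(0, j - p)
                    j1 = min(ww, j + p + 1)
                    acc = 0.0
                    for ii in range(i0, i1):
                        for jj in range(j0, j1):
                            acc += x[b, ch, ii, jj]
                    y[b, ch, i, j] = acc / ((i1 - i0) * (j1 - j0))


@njit(cache=True, fastmath=True)
def avgpool_backward(dy, k, dx):
    n, c, h, ww = dy.shape
    p = k // 2
    for b in range(n):
        for ch in range(c):
            for i in range(h):
                i0 = max(0, i - p)
                i1 = min(h, i + p + 1)
                for j in range(ww):
                    j0 = max(0, j - p)
                    j1 = min(ww, j + p + 1)
                    g = dy[b, ch, i, j] / ((i1 - i0) * (j1 - j0))
                    for ii in range(i0, i1):
                        for jj in range(j0, j1):
                            dx[b, ch, ii, jj] += g
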