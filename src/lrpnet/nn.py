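"""Minimal numpy neural-network engine used by the LRPNet classifier.

Explicit forward/backward layers in NCHW layout, with just the pieces
the architecture needs: 1x1 (pointwise) convolution, depthwise 3x3
convolution, batch normalization, ReLU, same-padded average pooling,
efficient channel attention, global average pooling, a linear head,
softmax cross-entropy, and an Adam optimizer.  Gradients are exact (the
test suite checks every layer against finite differences); all
randomness flows through an explicit numpy Generator.
"""

from __future__ import annotations

import numpy as np

try:  # compiled kernels for the two memory-bound layers
    from . import _kernels

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba not installed
    _kernels = None
    HAVE_NUMBA = False

__all__ = [
    "Parameter",
    "Module",
    "Conv1x1",
    "DepthwiseConv3x3",
    "BatchNorm2d",
    "ReLU",
    "AvgPoolSame",
    "GlobalAvgPool",
    "Linear",
    "ECAGate",
    "softmax",
    "SoftmaxCrossEntropy",
    "Adam",
    "eca_kernel_size",
]


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base layer: forward caches what backward needs."""

    training: bool = True

    def params(self) -> list[Parameter]:
        return []

    def set_training(self, mode: bool) -> None:
        self.training = mode

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv1x1(Module):
    """Pointwise convolution: a per-pixel linear map across channels."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float32):
        # He initialization, fan-out scaled (fan_out = c_out for a 1x1 kernel)
        std = np.sqrt(2.0 / c_out)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(c_in, c_out)).astype(dtype), "conv1x1.weight"
        )
        self.bias = Parameter(np.zeros(c_out, dtype=dtype), "conv1x1.bias") if bias else None
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        self._x3 = np.ascontiguousarray(x).reshape(n, c, h * w)
        self._shape = (n, h, w)
        y = np.matmul(self.weight.value.T, self._x3)  # (n, c_out, h*w)
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        return y.reshape(n, self.c_out, h, w)

    def backward(self, dy):
        n, h, w = self._shape
        dy3 = np.ascontiguousarray(dy).reshape(n, self.c_out, h * w)
        self.weight.grad += np.tensordot(self._x3, dy3, axes=([0, 2], [0, 2]))
        if self.bias is not None:
            self.bias.grad += dy3.sum(axis=(0, 2))
        dx = np.matmul(self.weight.value, dy3)  # (n, c_in, h*w)
        return dx.reshape(n, self.c_in, h, w)


class DepthwiseConv3x3(Module):
    """Per-channel 3x3 convolution, stride 1, zero 'same' padding."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 bias: bool = False, dtype=np.float32):
        std = np.sqrt(2.0 / 9.0)  # fan_out = k*k per channel
        self.weight = Parameter(
            rng.normal(0.0, std, size=(channels, 3, 3)).astype(dtype), "dw3x3.weight"
        )
        self.bias = Parameter(np.zeros(channels, dtype=dtype), "dw3x3.bias") if bias else None
        self.channels = channels

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        self._x = np.ascontiguousarray(x)
        y = np.empty_like(self._x)
        if HAVE_NUMBA:
            _kernels.dw3x3_forward(self._x, self.weight.value, y)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            y[...] = 0.0
            for i in range(3):
                for j in range(3):
                    y += (self.weight.value[:, i, j][None, :, None, None]
                          * xp[:, :, i : i + h, j : j + w])
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, dy):
        x = self._x
        n, c, h, w = x.shape
        dy = np.ascontiguousarray(dy)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        if HAVE_NUMBA:
            dx = np.empty_like(x)
            _kernels.dw3x3_backward(x, self.weight.value, dy,
                                    self.weight.grad, dx)
            return dx
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                self.weight.grad[:, i, j] += np.einsum(
                    "nchw,nchw->c", dy, xp[:, :, i : i + h, j : j + w]
                )
                dxp[:, :, i : i + h, j : j + w] += (
                    self.weight.value[:, i, j][None, :, None, None] * dy
                )
        return dxp[:, :, 1:-1, 1:-1]


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.channels = channels
        self._refresh_count: int | None = None

    def start_stats_refresh(self) -> None:
        """Switch running-stat updates to a cumulative average.

        Used to recalibrate the running statistics with forward passes
        after training: the cumulative average over one sweep of the
        training set equals the mean of the per-batch statistics, which
        short training runs never reach with exponential updates.
        """
        self.running_mean[...] = 0.0
        self.running_var[...] = 0.0
        self._refresh_count = 0

    def end_stats_refresh(self) -> None:
        self._refresh_count = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = np.einsum("nchw,nchw->c", x, x) / (
                x.shape[0] * x.shape[2] * x.shape[3]
            ) - mean * mean
            np.maximum(var, 0.0, out=var)
            if self._refresh_count is not None:
                mom = 1.0 / (self._refresh_count + 1)
                self._refresh_count += 1
            else:
                mom = self.momentum
            self.running_mean = (1 - mom) * self.running_mean + mom * mean
            self.running_var = (1 - mom) * self.running_var + mom * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        mean = mean.astype(x.dtype)
        self._x = np.ascontiguousarray(x)
        self._mean, self._inv = mean, inv
        if HAVE_NUMBA:
            y = np.empty_like(self._x)
            _kernels.bn_forward(self._x, mean, inv, self.gamma.value,
                                self.beta.value, y)
            return y
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dy):
        x, mean, inv = self._x, self._mean, self._inv
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        if HAVE_NUMBA:
            dy = np.ascontiguousarray(dy)
            sum_dy = np.zeros(self.channels, dtype=np.float64)
            sum_dy_xhat = np.zeros(self.channels, dtype=np.float64)
            _kernels.bn_reduce(x, dy, mean, inv, sum_dy, sum_dy_xhat)
            sum_dy = sum_dy.astype(x.dtype)
            sum_dy_xhat = sum_dy_xhat.astype(x.dtype)
            self.gamma.grad += sum_dy_xhat
            self.beta.grad += sum_dy
            dx = np.empty_like(x)
            _kernels.bn_backward_dx(
                x, dy, mean, inv, self.gamma.value, sum_dy, sum_dy_xhat,
                float(m), self.training, dx,
            )
            return dx
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        sum_dy = np.einsum("nchw->c", dy)
        sum_dy_xhat = np.einsum("nchw,nchw->c", dy, xhat)
        self.gamma.grad += sum_dy_xhat
        self.beta.grad += sum_dy
        if not self.training:
            return dy * (self.gamma.value * inv)[None, :, None, None]
        g = (self.gamma.value * inv)[None, :, None, None]
        return g * (
            dy
            - (sum_dy / m)[None, :, None, None]
            - xhat * (sum_dy_xhat / m)[None, :, None, None]
        )


class ReLU(Module):
    def forward(self, x):
        self._y = np.maximum(x, 0)
        return self._y

    def backward(self, dy):
        if HAVE_NUMBA and dy.ndim == 4:
            dy = np.ascontiguousarray(dy)
            dx = np.empty_like(dy)
            _kernels.relu_backward(dy, self._y, dx)
            return dx
        return dy * (self._y > 0)


class AvgPoolSame(Module):
    """k x k average pooling, stride 1, same zero padding.

    Border averages divide by the number of in-bounds taps (padding does
    not count), matching the pooling token mixer of the original
    PoolFormer block.
    """

    def __init__(self, k: int = 3):
        if k % 2 == 0 or k < 1:
            raise ValueError(f"pool size must be odd and positive, got {k}")
        self.k = k

    def _divisor(self, h: int, w: int) -> np.ndarray:
        p = self.k // 2
        ones = np.ones((h, w))
        op = np.pad(ones, p)
        div = np.zeros((h, w))
        for i in range(self.k):
            for j in range(self.k):
                div += op[i : i + h, j : j + w]
        return div

    def forward(self, x):
        n, c, h, w = x.shape
        self._hw = (h, w)
        if HAVE_NUMBA:
            x = np.ascontiguousarray(x)
            y = np.empty_like(x)
            _kernels.avgpool_forward(x, self.k, y)
            return y
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        acc = np.zeros_like(x)
        for i in range(self.k):
            for j in range(self.k):
                acc += xp[:, :, i : i + h, j : j + w]
        return acc / self._divisor(h, w).astype(x.dtype)

    def backward(self, dy):
        h, w = self._hw
        p = self.k // 2
        if HAVE_NUMBA:
            dy = np.ascontiguousarray(dy)
            dx = np.zeros_like(dy)
            _kernels.avgpool_backward(dy, self.k, dx)
            return dx
        dyn = dy / self._divisor(h, w).astype(dy.dtype)
        dxp = np.zeros(
            (dy.shape[0], dy.shape[1], h + 2 * p, w + 2 * p), dtype=dy.dtype
        )
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dyn
        return dxp[:, :, p : p + h, p : p + w]


class GlobalAvgPool(Module):
    """Collapse each channel map to its mean: (N, C, H, W) -> (N, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = np.sqrt(2.0 / n_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(n_in, n_out)).astype(dtype), "linear.weight"
        )
        self.bias = Parameter(np.zeros(n_out, dtype=dtype), "linear.bias")

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy):
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value.T


def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive ECA kernel: nearest odd to |log2(C)/gamma + b/gamma|."""
    t = int(abs(np.log2(channels) / gamma + b / gamma))
    return t if t % 2 == 1 else t + 1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class ECAGate(Module):
    """Efficient channel attention.

    Global average pooling produces one descriptor per channel; a small
    1-D convolution across the channel axis (no bias) followed by a
    sigmoid yields a gate in (0, 1) that multiplies each channel map.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 kernel: int | None = None, dtype=np.float32):
        k = eca_kernel_size(channels) if kernel is None else int(kernel)
        if k % 2 == 0 or k < 1:
            raise ValueError(f"ECA kernel must be odd and positive, got {k}")
        if channels < 1:
            raise ValueError("ECA needs at least one channel")
        std = np.sqrt(1.0 / k)
        self.weight = Parameter(
            rng.normal(0.0, std, size=k).astype(dtype), "eca.weight"
        )
        self.k = k
        self.channels = channels

    def params(self):
        return [self.weight]

    def _conv1d(self, s: np.ndarray) -> np.ndarray:
        # s: (N, C); zero-padded same convolution across the channel axis
        p = self.k // 2
        sp = np.pad(s, ((0, 0), (p, p)))
        z = np.zeros_like(s)
        for j in range(self.k):
            z += self.weight.value[j] * sp[:, j : j + s.shape[1]]
        return z

    def forward(self, x):
        n, c, h, w = x.shape
        x = np.ascontiguousarray(x)
        s = x.mean(axis=(2, 3))  # (N, C)
        z = self._conv1d(s)
        g = _sigmoid(z)
        self._x, self._s, self._g = x, s, g
        self._hw = (h, w)
        if HAVE_NUMBA:
            y = np.empty_like(x)
            _kernels.mul_gate(x, g, y)
            return y
        return x * g[:, :, None, None]

    def backward(self, dy):
        x, s, g = self._x, self._s, self._g
        h, w = self._hw
        c = s.shape[1]
        p = self.k // 2
        if HAVE_NUMBA:
            dy = np.ascontiguousarray(dy)
            dg = np.empty_like(s)
            _kernels.dot_hw(dy, x, dg)
        else:
            dg = (dy * x).sum(axis=(2, 3))  # (N, C)
        dz = dg * g * (1.0 - g)
        sp = np.pad(s, ((0, 0), (p, p)))
        dsp = np.zeros_like(sp)
        for j in range(self.k):
            self.weight.grad[j] += float(np.sum(dz * sp[:, j : j + c]))
            dsp[:, j : j + c] += self.weight.value[j] * dz
        ds = dsp[:, p : p + c]
        if HAVE_NUMBA:
            dx = np.empty_like(x)
            _kernels.gate_backward_dx(dy, x, g, (ds / (h * w)).astype(x.dtype), dx)
            return dx
        return dy * g[:, :, None, None] + ds[:, :, None, None] / (h * w)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SoftmaxCrossEntropy:
    """Mean cross-entropy over the batch, from raw logits."""

    def forward(self, logits: np.ndarray, y: np.ndarray) -> float:
        self._p = softmax(logits)
        self._y = y
        n = len(y)
        eps = np.finfo(self._p.dtype).tiny
        return float(-np.mean(np.log(self._p[np.arange(n), y] + eps)))

    def backward(self) -> np.ndarray:
        n = len(self._y)
        d = self._p.copy()
        d[np.arange(n), self._y] -= 1.0
        return d / n


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
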