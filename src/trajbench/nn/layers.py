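"""Neural-network layers built on the autodiff core.

Layers are lightweight callables operating on channel-last tensors:
sequences are (N, T, C), images are (N, H, W, C).  Each layer exposes its
trainable tensors through ``params()``; a ``train`` flag switches dropout
and batch-norm between training and inference behaviour.
"""

from __future__ import annotations

import numpy as np

from trajbench.nn import autograd as ag
from trajbench.nn.autograd import Tensor, DTYPE


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(DTYPE), requires_grad=True)


class Layer:
    def params(self) -> list[Tensor]:
        return []

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = glorot(rng, in_dim, out_dim, (in_dim, out_dim))
        self.b = Tensor(np.zeros(out_dim, dtype=DTYPE), requires_grad=True)

    def params(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x @ self.W + self.b


class Conv1D(Layer):
    """Stride-1 'same' 1-D convolution on (N, T, C)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.pad = (kernel - 1) // 2
        self.odd_fix = (kernel - 1) % 2  # even kernels need asymmetric padding
        fan_in = kernel * in_ch
        self.W = glorot(rng, fan_in, out_ch, (fan_in, out_ch))
        self.b = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)

    def params(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        cols = ag.unfold1d(x, self.kernel, self.pad + self.odd_fix)
        y = cols @ self.W + self.b
        if self.odd_fix:
            y = y[:, : x.shape[1], :]
        return y


class Conv2D(Layer):
    """Stride-1 'same' 2-D convolution on (N, H, W, C); odd kernels only."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        assert kernel % 2 == 1
        self.kernel = kernel
        self.pad = (kernel - 1) // 2
        fan_in = kernel * kernel * in_ch
        self.W = glorot(rng, fan_in, out_ch, (fan_in, out_ch))
        self.b = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)

    def params(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        cols = ag.unfold2d(x, self.kernel, self.pad)
        return cols @ self.W + self.b


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.reshape(-1)
            self.running_var = m * self.running_var + (1 - m) * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma + self.beta


class LayerNorm(Layer):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma + self.beta


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = float(rate)
        self.rng = rng

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        if not train or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)


class LSTM(Layer):
    """Standard LSTM over (N, T, C); returns the last hidden state (N, H)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.Wx = glorot(rng, in_dim, 4 * hidden, (in_dim, 4 * hidden))
        self.Wh = glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden))
        b = np.zeros(4 * hidden, dtype=DTYPE)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        N, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((N, H), dtype=DTYPE))
        c = Tensor(np.zeros((N, H), dtype=DTYPE))
        for t in range(T):
            xt = x[:, t, :]
            gates = xt @ self.Wx + h @ self.Wh + self.b
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class MultiHeadAttention(Layer):
    """Scaled dot-product self-attention with h heads on (N, T, D)."""

    def __init__(self, dim: int, heads: int, head_size: int, rng: np.random.Generator):
        self.heads = heads
        self.head_size = head_size
        inner = heads * head_size
        self.Wq = glorot(rng, dim, inner, (dim, inner))
        self.Wk = glorot(rng, dim, inner, (dim, inner))
        self.Wv = glorot(rng, dim, inner, (dim, inner))
        self.Wo = glorot(rng, inner, dim, (inner, dim))

    def params(self):
        return [self.Wq, self.Wk, self.Wv, self.Wo]

    def _split(self, x: Tensor, N: int, T: int) -> Tensor:
        return x.reshape(N, T, self.heads, self.head_size).transpose((0, 2, 1, 3))

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        N, T, _ = x.shape
        q = self._split(x @ self.Wq, N, T)
        k = self._split(x @ self.Wk, N, T)
        v = self._split(x @ self.Wv, N, T)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(self.head_size))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(N, T, self.heads * self.head_size)
        return out @ self.Wo


def gap1d(x: Tensor) -> Tensor:
    """Global average pooling over the time axis of (N, T, C)."""
    return x.mean(axis=1)


def gap2d(x: Tensor) -> Tensor:
    """Global average pooling over the spatial axes of (N, H, W, C)."""
    return x.mean(axis=(1, 2))
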