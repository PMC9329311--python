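"""Minimal reverse-mode automatic differentiation on numpy arrays.

A ``Tensor`` wraps an ndarray and records the operations applied to it; a
call to ``backward()`` on a scalar loss walks the tape in reverse
topological order and accumulates gradients.  The op set is exactly what
the architectures in :mod:`trajbench.model_zoo` need: broadcasted
arithmetic, (batched) matmul, the usual activations, axis reductions,
reshaping/indexing, im2col-style unfolds for convolution, max pooling, and
a fused softmax cross-entropy.  Computation is float32 throughout.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing ---------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        grad = grad.astype(DTYPE, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        a, b = self.data, other.data

        def backward(g):
            if self.requires_grad:
                if b.ndim == 2:
                    self._accum(g @ b.T)
                else:
                    self._accum(np.matmul(g, np.swapaxes(b, -1, -2)))
            if other.requires_grad:
                if b.ndim == 2:
                    dims = tuple(range(a.ndim - 1))
                    other._accum(np.tensordot(a, g, axes=(dims, dims)))
                else:
                    gb = np.matmul(np.swapaxes(a, -1, -2), g)
                    other._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(a, b), (self, other), backward)

    __matmul__ = matmul

    # -- activations ------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        return Tensor._make(y, (self,), backward)

    def tanh(self):
        y = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y**2))

        return Tensor._make(y, (self,), backward)

    def exp(self):
        y = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * y)

        return Tensor._make(y, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        y = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / y)

        return Tensor._make(y, (self,), backward)

    # -- reductions / shaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes: tuple[int, ...]):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                gx = np.zeros(self.shape, dtype=DTYPE)
                np.add.at(gx, key, g)
                self._accum(gx)

        return Tensor._make(self.data[key], (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))

        return Tensor._make(y, (self,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def unfold1d(x: Tensor, kernel: int, pad: int) -> Tensor:
    """im2col for stride-1 1-D convolution.

    Input (N, T, C) -> output (N, T_out, kernel * C) with T_out = T + 2*pad
    - kernel + 1.
    """
    N, T, C = x.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    T_out = T + 2 * pad - kernel + 1
    cols = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=1)
    # cols: (N, T_out, C, kernel) -> (N, T_out, kernel, C)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(N, T_out, kernel * C)

    def backward(g):
        if not x.requires_grad:
            return
        gc = g.reshape(N, T_out, kernel, C)
        gx = np.zeros((N, T + 2 * pad, C), dtype=DTYPE)
        for k in range(kernel):
            gx[:, k : k + T_out, :] += gc[:, :, k, :]
        x._accum(gx[:, pad : pad + T, :])

    return Tensor._make(cols, (x,), backward)


def unfold2d(x: Tensor, kernel: int, pad: int) -> Tensor:
    """im2col for stride-1 2-D convolution.

    Input (N, H, W, C) -> (N, H_out, W_out, kernel*kernel*C).
    """
    N, H, W, C = x.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    H_out = H + 2 * pad - kernel + 1
    W_out = W + 2 * pad - kernel + 1
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(1, 2))
    # cols: (N, H_out, W_out, C, kernel, kernel) -> (..., kernel, kernel, C)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
    cols = cols.reshape(N, H_out, W_out, kernel * kernel * C)

    def backward(g):
        if not x.requires_grad:
            return
        gc = g.reshape(N, H_out, W_out, kernel, kernel, C)
        gx = np.zeros((N, H + 2 * pad, W + 2 * pad, C), dtype=DTYPE)
        for ki in range(kernel):
            for kj in range(kernel):
                gx[:, ki : ki + H_out, kj : kj + W_out, :] += gc[:, :, :, ki, kj, :]
        x._accum(gx[:, pad : pad + H, pad : pad + W, :])

    return Tensor._make(cols, (x,), backward)


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling along the time axis of (N, T, C)."""
    N, T, C = x.shape
    T_out = T // size
    xt = x.data[:, : T_out * size, :].reshape(N, T_out, size, C)
    y = xt.max(axis=2)
    mask = xt == y[:, :, None, :]
    counts = mask.sum(axis=2, keepdims=True)

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros((N, T, C), dtype=DTYPE)
        spread = mask * (g[:, :, None, :] / counts)
        gx[:, : T_out * size, :] = spread.reshape(N, T_out * size, C)
        x._accum(gx)

    return Tensor._make(y, (x,), backward)


def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling over the spatial axes of (N, H, W, C)."""
    N, H, W, C = x.shape
    H_out, W_out = H // size, W // size
    xt = x.data[:, : H_out * size, :, :][:, :, : W_out * size, :]
    xt = xt.reshape(N, H_out, size, W_out, size, C)
    y = xt.max(axis=(2, 4))
    mask = xt == y[:, :, None, :, None, :]
    counts = mask.sum(axis=(2, 4), keepdims=True)

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros((N, H, W, C), dtype=DTYPE)
        spread = mask * (g[:, :, None, :, None, :] / counts)
        gx[:, : H_out * size, : W_out * size, :] = spread.reshape(
            N, H_out * size, W_out * size, C
        )
        x._accum(gx)

    return Tensor._make(y, (x,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of 2-unit (or k-unit) softmax logits against int labels."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(labels)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))

    def backward(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accum(g * grad / n)

    return Tensor._make(loss, (logits,), backward)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Plain softmax on raw logits (inference path, no graph)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
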