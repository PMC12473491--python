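"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the point-cloud segmentation network: broadcast
arithmetic, matmul, elementwise nonlinearities, reductions with axis
support, gather, concatenation and depthwise 1-D convolution. Gradients
are accumulated by topological backward traversal, and every operator is
validated against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over the axes that broadcasting expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make numpy defer to the reflected operators below
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return self._make(self.data / other.data, (self, other), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def backward(g):
            self._accumulate(
                _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
            )
            other._accumulate(
                _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)
            )

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accumulate(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions & reshaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # route the gradient to the first maximum only (deterministic ties)
        first = np.cumsum(mask, axis=axis) == 1
        mask = mask & first

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(g * mask)

        result = out_data if keepdims else out_data.squeeze(axis=axis)
        return self._make(result, (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes) -> "Tensor":
        inverse = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inverse))

        return self._make(self.data.transpose(axes), (self,), backward)

    def gather(self, index: np.ndarray) -> "Tensor":
        """Advanced indexing along axis 0 (index may be multi-dimensional)."""
        index = np.asarray(index)

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, index.reshape(-1), g.reshape(-1, *self.shape[1:]))
            self._accumulate(acc)

        return self._make(self.data[index], (self,), backward)

    # -- convolution -------------------------------------------------------

    def dwconv(self, kernel: "Tensor", axis: int) -> "Tensor":
        """Depthwise 1-D convolution with zero 'same' padding.

        ``self`` has channels on the last axis; ``kernel`` is (k, C) and is
        applied independently per channel, sliding along ``axis``.
        """
        k = kernel.shape[0]
        pad_lo = (k - 1) // 2
        pad_hi = k - 1 - pad_lo
        pads = [(0, 0)] * self.data.ndim
        pads[axis] = (pad_lo, pad_hi)
        padded = np.pad(self.data, pads)
        length = self.shape[axis]
        out_data = np.zeros_like(self.data)
        for j in range(k):
            sl = [slice(None)] * self.data.ndim
            sl[axis] = slice(j, j + length)
            out_data += padded[tuple(sl)] * kernel.data[j]

        def backward(g):
            grad_pad = np.zeros_like(padded)
            grad_k = np.zeros_like(kernel.data)
            for j in range(k):
                sl = [slice(None)] * self.data.ndim
                sl[axis] = slice(j, j + length)
                grad_pad[tuple(sl)] += g * kernel.data[j]
                grad_k[j] = (g * padded[tuple(sl)]).reshape(-1, self.shape[-1]).sum(axis=0)
            trim = [slice(None)] * self.data.ndim
            trim[axis] = slice(pad_lo, pad_lo + length)
            self._accumulate(grad_pad[tuple(trim)])
            kernel._accumulate(grad_k)

        return self._make(out_data, (self, kernel), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis, splitting the gradient back."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))

    def backward(g):
        start = 0
        for t, size in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + size)
            t._accumulate(g[tuple(sl)])
            start += size

    if any(t.requires_grad or t._prev for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def _gather_rows(self: Tensor, cols: np.ndarray) -> Tensor:
    """Pick one column per row: out[i] = self[i, cols[i]]."""
    cols = np.asarray(cols)
    rows = np.arange(self.shape[0])

    def backward(g):
        acc = np.zeros_like(self.data)
        np.add.at(acc, (rows, cols), g)
        self._accumulate(acc)

    return self._make(self.data[rows, cols], (self,), backward)


Tensor.gather_rows = _gather_rows


class Adam:
    """Adam optimiser with classic (coupled) L2 weight decay."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 0.001,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
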