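"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray``,
records its parents and a backward closure when gradients are enabled, and
``backward()`` runs the chain rule over the topologically sorted graph.
It supports exactly the operations the recurrent models in this package
need (broadcast arithmetic, matmul, tanh/sigmoid/relu, log-softmax,
reductions, concatenation, gather/select).  Use :class:`no_grad` around
pure-inference passes so no graph is retained.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True

DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the dtype used for all tensors (float32 for heavy training runs)."""
    global DTYPE
    DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return DTYPE


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily switch the tensor dtype (e.g. float32 for heavy runs)."""
    global DTYPE
    prev = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = prev


class no_grad(contextlib.ContextDecorator):
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = grad.copy() if isinstance(grad, np.ndarray) else np.asarray(grad)
        else:
            self.grad += grad

    # ---------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    # ---------------------------------------------------------- nonlinear
    def tanh(self):
        t = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        return Tensor._make(t, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def relu(self):
        m = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * m)

        return Tensor._make(self.data * m, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        return Tensor._make(e, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    # ---------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ---------------------------------------------------------- structure
    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    # ---------------------------------------------------------- autograd
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# ---------------------------------------------------------------- functions
def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather: ``weight[idx]`` with scatter-add backward."""
    idx = np.asarray(idx)
    out_data = weight.data[idx]

    def backward(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, idx, g)
            weight._accum(full)

    return Tensor._make(out_data, (weight,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    probs = np.exp(out_data)

    def backward(g):
        if x.requires_grad:
            x._accum(g - probs * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def select_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Pick one entry per row along the last axis: out[b] = x[b, idx[b]]."""
    idx = np.asarray(idx)
    rows = np.arange(x.data.shape[0])
    out_data = x.data[rows, idx]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, (rows, idx), g)
            x._accum(full)

    return Tensor._make(out_data, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)
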