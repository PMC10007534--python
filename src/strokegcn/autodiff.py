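"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape (the implicit DAG of parents).  Calling :meth:`Tensor.backward`
on a scalar result accumulates gradients into every upstream tensor created
with ``requires_grad=True``.  Only the handful of operations needed by the
stroke classifier are implemented; all arithmetic is float64.

Broadcasting follows numpy semantics: gradients flowing into a broadcast
operand are summed over the broadcast axes (``_unbroadcast``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "sigmoid",
    "tanh",
    "relu",
    "exp",
    "log",
    "softmax",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # Leading axes added by broadcasting.
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # Axes of size 1 that were stretched.
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}{tag}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph construction ------------------------------------------------
    def _tracked(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def _needs_grad(self, *others: "Tensor") -> bool:
        return self._tracked() or any(o._tracked() for o in others)

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data)
        if self._needs_grad(other):
            def backward(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accumulate(_unbroadcast(g, a.data.shape))
                if b.requires_grad or b._parents:
                    b._accumulate(_unbroadcast(g, b.data.shape))
            out._parents, out._backward = (self, other), backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        if self.requires_grad or self._parents:
            def backward(g, a=self):
                a._accumulate(-g)
            out._parents, out._backward = (self,), backward
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data)
        if self._needs_grad(other):
            def backward(g, a=self, b=other):
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))
            out._parents, out._backward = (self, other), backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data)
        if self._needs_grad(other):
            def backward(g, a=self, b=other):
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))
            out._parents, out._backward = (self, other), backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data)
        if self._needs_grad(other):
            def backward(g, a=self, b=other):
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.swapaxes(a.data, -1, -2) @ g
                a._accumulate(_unbroadcast(ga, a.data.shape))
                b._accumulate(_unbroadcast(gb, b.data.shape))
            out._parents, out._backward = (self, other), backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx])
        if self.requires_grad or self._parents:
            def backward(g, a=self, idx=idx):
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accumulate(full)
            out._parents, out._backward = (self,), backward
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape))
        if self.requires_grad or self._parents:
            def backward(g, a=self):
                a._accumulate(g.reshape(a.data.shape))
            out._parents, out._backward = (self,), backward
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        if self.requires_grad or self._parents:
            def backward(g, a=self, axis=axis, keepdims=keepdims):
                if axis is None:
                    a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                else:
                    if not keepdims:
                        g = np.expand_dims(g, axis)
                    a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            out._parents, out._backward = (self,), backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- backward pass -----------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topological sort; graphs can be deep (RNN)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities -------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    # numerically stable two-branch evaluation
    d = x.data
    y = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.clip(d, 0, None))),
                 np.exp(np.clip(d, None, 0)) / (1.0 + np.exp(np.clip(d, None, 0))))
    out = Tensor(y)
    if x.requires_grad or x._parents:
        def backward(g, a=x, y=y):
            a._accumulate(g * y * (1.0 - y))
        out._parents, out._backward = (x,), backward
    return out


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = np.tanh(x.data)
    out = Tensor(y)
    if x.requires_grad or x._parents:
        def backward(g, a=x, y=y):
            a._accumulate(g * (1.0 - y * y))
        out._parents, out._backward = (x,), backward
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0))
    if x.requires_grad or x._parents:
        def backward(g, a=x):
            a._accumulate(g * (a.data > 0))
        out._parents, out._backward = (x,), backward
    return out


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = np.exp(x.data)
    out = Tensor(y)
    if x.requires_grad or x._parents:
        def backward(g, a=x, y=y):
            a._accumulate(g * y)
        out._parents, out._backward = (x,), backward
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data))
    if x.requires_grad or x._parents:
        def backward(g, a=x):
            a._accumulate(g / a.data)
        out._parents, out._backward = (x,), backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Shift-invariant softmax; the max is detached so gradients are exact."""
    x = as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = exp(x - shift)
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad or t._parents for t in tensors):
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g, ts=tensors, splits=splits, axis=axis):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                t._accumulate(piece)
        out._parents, out._backward = tuple(tensors), backward
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
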