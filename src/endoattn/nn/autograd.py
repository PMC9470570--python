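"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps a float64 ``ndarray``
and records the operations that produced it.  Calling :meth:`Tensor.backward`
on a scalar walks the graph in reverse topological order and accumulates
gradients into every tensor created with ``requires_grad=True``.

Only the operations needed by the convolutional layers in this package are
provided; broadcasting is supported for elementwise arithmetic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (14+ blocks)
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- elementwise arithmetic ---------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def bw(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        return Tensor(a * b, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            return (g.reshape(old),)

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def sum(self):
        def bw(g):
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor(self.data.sum(), parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        data = self.data.mean(axis=axis, keepdims=keepdims)
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape) / n,)

        return Tensor(data, parents=(self,), backward=bw)


class Parameter(Tensor):
    """A trainable tensor; ``init_kind`` drives deterministic initialization."""

    __slots__ = ("init_kind",)

    def __init__(self, data, init_kind: str = "weight"):
        super().__init__(data, requires_grad=True)
        self.init_kind = init_kind


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
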