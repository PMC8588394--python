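"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
remembers how it was produced, so calling :meth:`Tensor.backward` on a
scalar loss accumulates ``grad`` on every parameter that contributed to it.
Only the operations the recurrent/convolutional model zoo needs are
implemented; all of them broadcast like numpy and reduce gradients back to
the operand shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "maximum",
    "stack_last",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the recipe to backpropagate through it."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs of 25-step RNNs overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(self.data / other.data, _parents=(self, other), _backward=bwd)

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            # generalized for batched operands: contract over broadcast axes
            if self.requires_grad:
                gs = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(gs, self.data.shape))
            if other.requires_grad:
                go = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(go, other.data.shape))

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bwd)

    # ------------------------------------------------------------ elementwise
    def tanh(self):
        out = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out**2))

        return Tensor(out, _parents=(self,), _backward=bwd)

    def sigmoid(self):
        x = self.data
        out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out * (1.0 - out))

        return Tensor(out, _parents=(self,), _backward=bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bwd)

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = np.where(self.data > 0, self.data, neg)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, neg + alpha))

        return Tensor(out, _parents=(self,), _backward=bwd)

    def exp(self):
        out = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out)

        return Tensor(out, _parents=(self,), _backward=bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    def square(self):
        return self * self

    def sqrt(self):
        out = np.sqrt(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out)

        return Tensor(out, _parents=(self,), _backward=bwd)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=bwd)

    def __getitem__(self, idx):
        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor(self.data[idx], _parents=(self,), _backward=bwd)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,), _backward=bwd
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``, splitting the gradient back."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bwd,
    )


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; the gradient follows the winning operand (ties -> a)."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    take_a = a.data >= b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * ~take_a, b.data.shape))

    return Tensor(np.where(take_a, a.data, b.data), _parents=(a, b), _backward=bwd)


def stack_last(tensors: list[Tensor]) -> Tensor:
    """Stack equal-shape tensors along a new second-to-last axis.

    Used to reassemble per-timestep hidden states (batch, units) into a
    sequence (batch, steps, units).
    """
    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(g[..., i, :])

    return Tensor(
        np.stack([t.data for t in tensors], axis=-2),
        _parents=tuple(tensors),
        _backward=bwd,
    )
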