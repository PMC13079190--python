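"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the stroke network needs: broadcasted
arithmetic, matrix products, slicing/concatenation (for causal dilated
convolutions), reductions, elementwise nonlinearities and a numerically
stable log-softmax.  Gradients are accumulated by topological-order
backpropagation from a scalar loss; correctness is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np

__all__ = ["Tensor", "concat", "relu", "log_softmax", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over broadcast (size-1) axes
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ) -> None:
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- infrastructure --------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # materialize (grad may be a broadcast view)
            self.grad = np.array(np.broadcast_to(grad, self.data.shape))
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, True, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, True, (self, other))

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, True, (self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1.0)
        )
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, True, (self, other))

        def backward(g: np.ndarray) -> None:
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.expand_dims(g, -1) * b if a.ndim > 1 else np.outer(g, b)
                gb = (np.expand_dims(g, -1) * a).reshape(-1, a.shape[-1]).sum(0) \
                    if a.ndim > 1 else g * a
                self._accumulate(_unbroadcast(np.asarray(ga), a.shape))
                other._accumulate(_unbroadcast(np.asarray(gb), b.shape))
                return
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    def __rmatmul__(self, other) -> "Tensor":
        return self._lift(other) @ self

    # -- shape ------------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(shape), True, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes: int) -> "Tensor":
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), True, (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], True, (self,))
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple)
            and all(isinstance(k, (int, slice)) for k in key)
        )

        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            if basic:  # basic slices never alias, so direct add suffices
                full[key] += g
            else:
                np.add.at(full, key, g)
            self._accumulate(full)

        out._backward = backward
        return out

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))

        def backward(g: np.ndarray) -> None:
            if axis is not None:
                axes = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    for ax in sorted(a % self.ndim for a in axes):
                        g = np.expand_dims(g, ax)
            self._accumulate(np.broadcast_to(g, self.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise ------------------------------------------------------

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, True, (self,))
        # close over the value array, not `out`, to keep the graph acyclic
        # for reference counting
        out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), True, (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self) -> "Tensor":
        val = np.tanh(self.data)
        out = Tensor(val, True, (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - val**2))
        return out

    def clip_min(self, lo: float) -> "Tensor":
        out = Tensor(np.maximum(self.data, lo), True, (self,))
        mask = self.data > lo  # boolean mask multiplies as 0/1
        out._backward = lambda g: self._accumulate(g * mask)
        return out


def relu(x: Tensor) -> Tensor:
    return x.clip_min(0.0)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 True, tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(start, stop)
            t._accumulate(g[tuple(idx)])

    out._backward = backward
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax along `axis`."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()
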