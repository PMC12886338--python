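"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the model and objectives need: broadcasted
arithmetic, matmul, reductions, elementwise nonlinearities, row gathering,
concatenation, log-determinant, and a gradient-reversal node for
domain-adversarial branches. Everything is float64; graphs are built eagerly
and freed after :meth:`Tensor.backward`.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "grad_reverse", "inv", "logdet"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self._parents)

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this node (scalar unless `grad` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            self._accum(g)
            other._accum(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data ** 2)
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        out._backward = bw
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / out.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data ** 2))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def softplus(self):
        # numerically stable log(1 + e^x)
        out_data = np.logaddexp(0.0, self.data)
        out = Tensor(out_data, parents=(self,))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out._backward = lambda g: self._accum(g * sig)
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- structural
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(
            np.asarray(g).reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))
        out._backward = lambda g: self._accum(np.asarray(g).T)
        return out

    def take_rows(self, indices):
        """Gather rows by integer index (backward scatter-adds)."""
        idx = np.asarray(indices, dtype=np.intp)
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, np.asarray(g))
            self._accum(full)
        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(np.asarray(g), splits,
                                              axis=axis)):
            t._accum(piece)
    out._backward = bw
    return out


def grad_reverse(x: Tensor, strength: float) -> Tensor:
    """Identity forward; backward multiplies the gradient by -strength."""
    x = as_tensor(x)
    out = Tensor(x.data, parents=(x,))
    out._backward = lambda g: x._accum(-float(strength) * np.asarray(g))
    return out


def inv(a: Tensor) -> Tensor:
    """Matrix inverse; grad is -A^-T g A^-T."""
    a = as_tensor(a)
    ia = np.linalg.inv(a.data)
    out = Tensor(ia, parents=(a,))
    out._backward = lambda g: a._accum(-ia.T @ np.asarray(g) @ ia.T)
    return out


def logdet(a: Tensor) -> Tensor:
    """log|det A| for a positive-definite matrix; grad is inv(A)^T."""
    a = as_tensor(a)
    sign, val = np.linalg.slogdet(a.data)
    if sign <= 0:
        raise np.linalg.LinAlgError("logdet requires a positive determinant")
    out = Tensor(val, parents=(a,))
    inv = np.linalg.inv(a.data)
    out._backward = lambda g: a._accum(np.asarray(g) * inv.T)
    return out
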