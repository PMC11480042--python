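"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the package's variational Gaussian-process
objective and multilayer-perceptron training loops need: broadcasting
elementwise arithmetic, matrix products, reductions, ``exp``/``log``/``sqrt``,
``relu``, ``log_softmax``, triangular masking, Cholesky factorization and
triangular solves.  Gradients of the linear-algebra primitives follow the
standard adjoint rules (for the Cholesky factor, the Iain-Murray phi-form) and
are validated against central finite differences in the test suite.

Design notes
------------
* A :class:`Tensor` wraps an ``ndarray`` plus closure-based backward functions;
  :meth:`Tensor.backward` runs a topological sweep and accumulates ``grad``.
* Only tensors created with ``requires_grad=True`` (or downstream of one)
  participate in the tape; plain numpy arrays and scalars are treated as
  constants.
* Shapes produced by broadcasting are reduced back onto parent shapes by
  summation, so parameters can be scalars, vectors or matrices interchangeably.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.linalg


def _as_array(x) -> np.ndarray:
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    grad = np.asarray(grad, dtype=float)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=float)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    # -- tape -------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without an argument requires a scalar output")
            grad = np.ones_like(self.value)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
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
        self.grad = np.asarray(grad, dtype=float).reshape(self.value.shape)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=float)
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def detach(self) -> "Tensor":
        return Tensor(self.value.copy())

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    @property
    def T(self):
        return transpose(self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value + b.value

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.value.shape))

    return Tensor(out_val, parents=(a, b), backward=backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value - b.value

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(-g, b.value.shape))

    return Tensor(out_val, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value * b.value

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.value, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.value, b.value.shape))

    return Tensor(out_val, parents=(a, b), backward=backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value / b.value

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g / b.value, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(-g * a.value / b.value**2, b.value.shape))

    return Tensor(out_val, parents=(a, b), backward=backward)


def _unary(a, out_val, dval) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * dval)

    return Tensor(out_val, parents=(a,), backward=backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.value)
    return _unary(a, out, out)


def log(a) -> Tensor:
    a = as_tensor(a)
    return _unary(a, np.log(a.value), 1.0 / a.value)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out = np.sqrt(a.value)
    return _unary(a, out, 0.5 / np.maximum(out, 1e-300))


def square(a) -> Tensor:
    a = as_tensor(a)
    return _unary(a, a.value**2, 2.0 * a.value)


def relu(a) -> Tensor:
    a = as_tensor(a)
    return _unary(a, np.maximum(a.value, 0.0), (a.value > 0).astype(float))


# ---------------------------------------------------------------------------
# shape ops and reductions
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    in_shape = a.value.shape

    def backward(g):
        if a.requires_grad:
            a.accumulate(g.reshape(in_shape))

    return Tensor(a.value.reshape(shape), parents=(a,), backward=backward)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.value.ndim)))
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a.accumulate(np.transpose(g, inv))

    return Tensor(np.transpose(a.value, axes), parents=(a,), backward=backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_val = a.value.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a.accumulate(np.broadcast_to(g, a.value.shape).copy())
            return
        g2 = g
        if not keepdims:
            g2 = np.expand_dims(g, axis)
        a.accumulate(np.broadcast_to(g2, a.value.shape).copy())

    return Tensor(out_val, parents=(a,), backward=backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.value.size
    else:
        n = a.value.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    out_val = np.concatenate([t.value for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate(g[tuple(idx)])

    return Tensor(out_val, parents=tuple(tensors), backward=backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value @ b.value

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.value, -1, -2) if b.value.ndim > 1 else np.outer(g, b.value)
            a.accumulate(_unbroadcast(ga, a.value.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.value, -1, -2) @ g if a.value.ndim > 1 else np.outer(a.value, g)
            b.accumulate(_unbroadcast(gb, b.value.shape))

    return Tensor(out_val, parents=(a, b), backward=backward)


# ---------------------------------------------------------------------------
# softmax family
# ---------------------------------------------------------------------------

def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.value - a.value.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_val = shifted - lse
    soft = np.exp(out_val)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor(out_val, parents=(a,), backward=backward)


def softmax_values(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain numpy softmax (no tape); used on the prediction path."""
    shifted = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# triangular structure
# ---------------------------------------------------------------------------

def tril(a, k: int = 0) -> Tensor:
    a = as_tensor(a)
    mask = np.tril(np.ones_like(a.value), k=k)
    return _unary(a, a.value * mask, mask)


def diag_part(a) -> Tensor:
    """Extract the diagonal of a square matrix."""
    a = as_tensor(a)
    n = a.value.shape[0]

    def backward(g):
        if a.requires_grad:
            out = np.zeros_like(a.value)
            out[np.arange(n), np.arange(n)] = g
            a.accumulate(out)

    return Tensor(np.diag(a.value).copy(), parents=(a,), backward=backward)


def diag_embed(v) -> Tensor:
    """Build a diagonal matrix from a vector."""
    v = as_tensor(v)

    def backward(g):
        if v.requires_grad:
            v.accumulate(np.diag(g).copy())

    return Tensor(np.diag(v.value), parents=(v,), backward=backward)


# ---------------------------------------------------------------------------
# Cholesky and triangular solves
# ---------------------------------------------------------------------------

def cholesky(a) -> Tensor:
    a = as_tensor(a)
    L = np.linalg.cholesky(a.value)

    def backward(g):
        if not a.requires_grad:
            return
        # phi-form adjoint of the Cholesky factor: halve the diagonal of the
        # lower triangle of L^T Lbar, conjugate by L^{-1}, symmetrize.
        n = L.shape[-1]
        phi = np.tril(L.T @ g)
        phi[np.arange(n), np.arange(n)] *= 0.5
        inner = scipy.linalg.solve_triangular(L, phi.T, lower=True, trans="T").T
        S = scipy.linalg.solve_triangular(L, inner, lower=True, trans="T")
        a.accumulate((S + S.T) / 2.0)

    return Tensor(L, parents=(a,), backward=backward)


def solve_triangular(L, b, trans: str = "N") -> Tensor:
    """Solve ``L y = b`` (``trans='N'``) or ``L^T y = b`` (``trans='T'``) for
    lower-triangular ``L``; ``b`` may carry multiple right-hand-side columns."""
    L, b = as_tensor(L), as_tensor(b)
    y = scipy.linalg.solve_triangular(L.value, b.value, lower=True, trans=trans)

    def backward(g):
        gb = scipy.linalg.solve_triangular(
            L.value, g, lower=True, trans="T" if trans == "N" else "N"
        )
        if b.requires_grad:
            b.accumulate(gb)
        if L.requires_grad:
            if trans == "N":
                gL = -np.tril(_mat(gb) @ _mat(y).T)
            else:
                gL = -np.tril(_mat(y) @ _mat(gb).T)
            L.accumulate(gL)

    return Tensor(y, parents=(L, b), backward=backward)


def _mat(x: np.ndarray) -> np.ndarray:
    return x[:, None] if x.ndim == 1 else x
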