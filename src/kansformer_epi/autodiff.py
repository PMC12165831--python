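"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
remembers how it was produced; ``Tensor.backward`` walks the tape in reverse
topological order accumulating vector-Jacobian products.  Only the operations
needed by the model family in this package are provided (broadcast
arithmetic, matmul, reductions, shape ops, fancy indexing, the sigmoid/tanh
family, 1-D convolution helpers and a B-spline basis primitive).

Gradients are plain ``ndarray``s stored on ``Tensor.grad``; call
``zero_grad`` (or the optimizer's) between steps.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block (inference / metric code)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_owns_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._owns_grad = False
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        # first contribution is stored by reference (it may alias a child's
        # gradient, which is only ever read after this point); a second
        # contribution triggers copy-on-write so the alias stays intact
        if self.grad is None:
            self.grad = grad
            self._owns_grad = False
        else:
            if not self._owns_grad:
                self.grad = self.grad.copy()
                self._owns_grad = True
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * e * self.data ** (e - 1.0))
        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.multiply.outer(g, other.data) if self.data.ndim > 1 else g * other.data
                    if self.data.ndim == 2 and g.ndim == 1:
                        ga = np.outer(g, other.data)
                    self._accumulate(_unbroadcast(ga, self.shape))
                else:
                    self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accumulate(_unbroadcast(np.outer(self.data, g), other.shape))
                else:
                    other._accumulate(
                        _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))
        return Tensor._make(out_data, (self, other), bw)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))
        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, key):
        out_data = self.data[key]

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)
        return Tensor._make(out_data, (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.shape).copy())
                else:
                    if not keepdims:
                        g = np.expand_dims(g, axis)
                    self._accumulate(np.broadcast_to(g, self.shape).copy())
        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max-reduce along one axis; ties send all gradient to the first hit."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        arg = self.data.argmax(axis=axis)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                idx = list(np.indices(arg.shape))
                idx.insert(axis if axis >= 0 else self.ndim + axis, arg)
                gg = g if keepdims is False else np.squeeze(g, axis=axis)
                np.add.at(full, tuple(idx), gg)
                self._accumulate(full)
        return Tensor._make(out_data, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities ------------------------------------------------

def exp(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = np.exp(t.data)

    def bw(g):
        if t.requires_grad:
            t._accumulate(g * out_data)
    return Tensor._make(out_data, (t,), bw)


def log(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = np.log(t.data)

    def bw(g):
        if t.requires_grad:
            t._accumulate(g / t.data)
    return Tensor._make(out_data, (t,), bw)


def tanh(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = np.tanh(t.data)

    def bw(g):
        if t.requires_grad:
            t._accumulate(g * (1.0 - out_data ** 2))
    return Tensor._make(out_data, (t,), bw)


def sigmoid(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = 1.0 / (1.0 + np.exp(-t.data))

    def bw(g):
        if t.requires_grad:
            t._accumulate(g * out_data * (1.0 - out_data))
    return Tensor._make(out_data, (t,), bw)


def relu(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = np.maximum(t.data, 0.0)

    def bw(g):
        if t.requires_grad:
            t._accumulate(g * (t.data > 0.0))
    return Tensor._make(out_data, (t,), bw)


def silu(t: Tensor) -> Tensor:
    """x * sigmoid(x), the base activation of the spline layers."""
    return t * sigmoid(t)


def clip(t: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the unclamped region."""
    t = as_tensor(t)
    out_data = np.clip(t.data, lo, hi)
    mask = (t.data > lo) & (t.data < hi)

    def bw(g):
        if t.requires_grad:
            t._accumulate(g * mask)
    return Tensor._make(out_data, (t,), bw)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])
    return Tensor._make(out_data, tuple(ts), bw)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in ts], axis=axis)

    def bw(g):
        gs = np.moveaxis(g, axis, 0)
        for t, gt in zip(ts, gs):
            if t.requires_grad:
                t._accumulate(gt)
    return Tensor._make(out_data, tuple(ts), bw)


def pad_last(t: Tensor, before: int, after: int) -> Tensor:
    """Zero-pad the last axis (used for same-padding convolutions)."""
    t = as_tensor(t)
    width = [(0, 0)] * (t.ndim - 1) + [(before, after)]
    out_data = np.pad(t.data, width)
    n = t.shape[-1]

    def bw(g):
        if t.requires_grad:
            sl = [slice(None)] * g.ndim
            sl[-1] = slice(before, before + n)
            t._accumulate(g[tuple(sl)])
    return Tensor._make(out_data, (t,), bw)


def dropout(t: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return t
    mask = (rng.random(t.shape) >= p) / (1.0 - p)
    return t * Tensor(mask)


# -- B-spline basis primitive ----------------------------------------------

def bspline_design(x: np.ndarray, knots: np.ndarray, order: int) -> np.ndarray:
    """Cox–de Boor evaluation of all B-spline basis functions at ``x``.

    ``knots`` is the extended (uniform) knot vector; returns an array of shape
    ``x.shape + (len(knots) - order - 1,)`` holding degree-``order`` basis
    values.  Pure numpy; no graph recording.
    """
    x = np.asarray(x, dtype=np.float64)
    basis, _ = _bspline_recurse(x, knots, order, want_lower=False)
    return basis


def _is_uniform(knots: np.ndarray) -> bool:
    d = np.diff(knots)
    return bool(np.allclose(d, d[0], rtol=1e-9, atol=0.0))


def _bspline_recurse(x: np.ndarray, knots: np.ndarray, order: int,
                     want_lower: bool):
    """Cox-de Boor recursion; optionally returns the order-1 lower basis too.

    Uniform knot vectors (the only kind the package constructs) take a fast
    path with scalar denominators; non-uniform vectors fall back to the
    guarded general recursion.
    """
    xe = x[..., None]
    b = ((xe >= knots[:-1]) & (xe < knots[1:])).astype(np.float64)
    lower = b if order == 0 else None
    uniform = _is_uniform(knots)
    step = knots[1] - knots[0]
    for d in range(1, order + 1):
        if want_lower and d == order:
            lower = b                 # degree order-1 basis
        if uniform:
            inv = 1.0 / (d * step)
            left = (xe - knots[: -(d + 1)]) * inv * b[..., :-1]
            right = (knots[d + 1:] - xe) * inv * b[..., 1:]
        else:
            left_den = knots[d:-1] - knots[: -(d + 1)]
            right_den = knots[d + 1:] - knots[1:-d]
            with np.errstate(divide="ignore", invalid="ignore"):
                left = np.where(left_den > 0,
                                (xe - knots[: -(d + 1)]) / left_den, 0.0) * b[..., :-1]
                right = np.where(right_den > 0,
                                 (knots[d + 1:] - xe) / right_den, 0.0) * b[..., 1:]
        b = left + right
    return b, lower


def _bspline_with_derivative(x: np.ndarray, knots: np.ndarray, order: int):
    basis, lower = _bspline_recurse(x, knots, order, want_lower=order >= 1)
    if order == 0:
        return basis, np.zeros_like(basis)
    # d/dx B_{j,k} = k [ B_{j,k-1}/(t_{j+k}-t_j) - B_{j+1,k-1}/(t_{j+k+1}-t_{j+1}) ]
    den1 = knots[order:-1] - knots[: -(order + 1)]
    den2 = knots[order + 1:] - knots[1:-order]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(den1 > 0, lower[..., :-1] / den1, 0.0)
        term2 = np.where(den2 > 0, lower[..., 1:] / den2, 0.0)
    return basis, order * (term1 - term2)


def bspline_basis(t: Tensor, knots: np.ndarray, order: int,
                  lo: float, hi: float) -> Tensor:
    """Differentiable B-spline basis with linear extension outside [lo, hi].

    Inside the grid the usual Cox–de Boor values are returned.  Outside, each
    basis function is extended by its first-order Taylor expansion from the
    clamped boundary point, which keeps the partition of unity exact
    everywhere and the gradient bounded.
    """
    t = as_tensor(t)
    # stay strictly inside so the half-open interval convention never drops
    # the right boundary point
    eps = (hi - lo) * 1e-9
    xc = np.clip(t.data, lo, hi - eps)
    basis, deriv = _bspline_with_derivative(xc, knots, order)
    delta = (t.data - xc)[..., None]
    out_data = basis + deriv * delta

    def bw(g):
        if t.requires_grad:
            t._accumulate((g * deriv).sum(axis=-1))
    return Tensor._make(out_data, (t,), bw)
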