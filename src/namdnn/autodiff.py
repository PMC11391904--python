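"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine records a tape of operations on :class:`Tensor` objects. Every
vector-Jacobian product is itself expressed through tape operations, so
gradients can be differentiated again (``grad(..., create_graph=True)``).
This is what lets the package treat forces as exact derivatives of the
energy model and still backpropagate a force loss into the parameters.

Only the operations the networks need are implemented; all arrays are
float64.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Iterable

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "grad",
    "no_grad",
    "add", "sub", "mul", "div", "neg", "power",
    "exp", "log", "sqrt", "tanh", "sin", "cos", "sigmoid", "softplus",
    "ssp", "square",
    "tsum", "tmean", "matmul", "reshape", "transpose",
    "getitem", "scatter", "gather", "segment_sum",
    "concatenate", "stack", "broadcast_to", "norm", "dot",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "parents", "requires")

    def __init__(self, value, parents=(), requires=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = parents  # tuple of (Tensor, vjp callable)
        self.requires = requires

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self):
        return float(self.value)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires={self.requires})"

    # -- operator sugar ---------------------------------------------------
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
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)


def tensor(value) -> Tensor:
    """Wrap a value as a constant (non-differentiable) tensor."""
    if isinstance(value, Tensor):
        return value
    return Tensor(value)


def parameter(value) -> Tensor:
    """Wrap a value as a differentiable leaf."""
    return Tensor(np.array(value, dtype=np.float64), requires=True)


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(value, parents) -> Tensor:
    """Build an output node, recording parents only when the tape is live."""
    if _GRAD_ENABLED:
        parents = tuple((p, fn) for p, fn in parents if p.requires)
        if parents:
            return Tensor(value, parents, True)
    return Tensor(value)


# ---------------------------------------------------------------------------
# broadcasting helper: reduce a gradient back to the operand's shape
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _lift(a), _lift(b)
    return _make(a.value + b.value, (
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(g, b.shape)),
    ))


def sub(a, b):
    a, b = _lift(a), _lift(b)
    return _make(a.value - b.value, (
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(neg(g), b.shape)),
    ))


def neg(a):
    a = _lift(a)
    return _make(-a.value, ((a, lambda g: neg(g)),))


def mul(a, b):
    a, b = _lift(a), _lift(b)
    return _make(a.value * b.value, (
        (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
        (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
    ))


def div(a, b):
    a, b = _lift(a), _lift(b)
    return _make(a.value / b.value, (
        (a, lambda g: _unbroadcast(div(g, b), a.shape)),
        (b, lambda g: _unbroadcast(neg(mul(g, div(a, mul(b, b)))), b.shape)),
    ))


def power(a, p: float):
    a = _lift(a)
    p = float(p)
    return _make(a.value ** p, (
        (a, lambda g: mul(g, mul(p, power(a, p - 1.0)))),
    ))


def square(a):
    a = _lift(a)
    return mul(a, a)


def exp(a):
    a = _lift(a)
    out = _make(np.exp(a.value), ((a, lambda g: mul(g, out)),))
    return out


def log(a):
    a = _lift(a)
    return _make(np.log(a.value), ((a, lambda g: div(g, a)),))


def sqrt(a):
    a = _lift(a)
    out = _make(np.sqrt(a.value), ((a, lambda g: div(g, mul(2.0, out))),))
    return out


def tanh(a):
    a = _lift(a)
    out = _make(np.tanh(a.value), (
        (a, lambda g: mul(g, sub(1.0, mul(out, out)))),
    ))
    return out


def sin(a):
    a = _lift(a)
    return _make(np.sin(a.value), ((a, lambda g: mul(g, cos(a))),))


def cos(a):
    a = _lift(a)
    return _make(np.cos(a.value), ((a, lambda g: neg(mul(g, sin(a)))),))


def sigmoid(a):
    a = _lift(a)
    val = 0.5 * (1.0 + np.tanh(0.5 * a.value))  # numerically stable
    out = _make(val, (
        (a, lambda g: mul(g, mul(out, sub(1.0, out)))),
    ))
    return out


def softplus(a):
    a = _lift(a)
    return _make(np.logaddexp(0.0, a.value), (
        (a, lambda g: mul(g, sigmoid(a))),
    ))


_LOG2 = float(np.log(2.0))


def ssp(a):
    """Shifted softplus ln(0.5 e^x + 0.5): smooth activation with ssp(0)=0."""
    return sub(softplus(a), _LOG2)


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = _lift(a)
    val = np.sum(a.value, axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        if not keepdims:
            kshape = list(a.shape)
            for ax in axes:
                kshape[ax % a.ndim] = 1
            g = reshape(g, tuple(kshape))
        return broadcast_to(g, a.shape)

    return _make(val, ((a, vjp),))


def tmean(a, axis=None, keepdims=False):
    a = _lift(a)
    if axis is None:
        n = a.value.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return div(tsum(a, axis=axis, keepdims=keepdims), float(n))


def reshape(a, shape):
    a = _lift(a)
    shape = tuple(shape)
    return _make(a.value.reshape(shape), (
        (a, lambda g: reshape(g, a.shape)),
    ))


def transpose(a, axes):
    a = _lift(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(np.transpose(a.value, axes), (
        (a, lambda g: transpose(g, inv)),
    ))


def broadcast_to(a, shape):
    a = _lift(a)
    shape = tuple(shape)
    return _make(np.broadcast_to(a.value, shape).copy(), (
        (a, lambda g: _unbroadcast(g, a.shape)),
    ))


def _swap_last(t):
    ax = list(range(t.ndim))
    ax[-1], ax[-2] = ax[-2], ax[-1]
    return transpose(t, ax)


def matmul(a, b):
    """Matrix product for stacked matrices (both operands ndim >= 2)."""
    a, b = _lift(a), _lift(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires ndim >= 2 on both operands")
    if a.ndim > 2 and b.ndim == 2:
        # collapse the batch axes into one 2-D GEMM (much faster than a
        # loop over many tiny stacked products)
        lead = a.shape[:-1]
        flat = _matmul2(reshape(a, (-1, a.shape[-1])), b)
        return reshape(flat, lead + (b.shape[1],))
    return _matmul_general(a, b)


def _matmul2(a, b):
    # both strictly 2-D
    val = a.value @ b.value
    return _make(val, (
        (a, lambda g: _matmul2(g, transpose(b, (1, 0)))),
        (b, lambda g: _matmul2(transpose(a, (1, 0)), g)),
    ))


def _matmul_general(a, b):
    val = a.value @ b.value
    return _make(val, (
        (a, lambda g: _unbroadcast(matmul(g, _swap_last(b)), a.shape)),
        (b, lambda g: _unbroadcast(matmul(_swap_last(a), g), b.shape)),
    ))


def dot(a, b, axis=-1, keepdims=False):
    return tsum(mul(a, b), axis=axis, keepdims=keepdims)


def norm(a, axis=-1, keepdims=False, eps=0.0):
    s = tsum(square(a), axis=axis, keepdims=keepdims)
    if eps:
        s = add(s, eps)
    return sqrt(s)


# ---------------------------------------------------------------------------
# indexing
# ---------------------------------------------------------------------------

def getitem(a, idx):
    a = _lift(a)
    return _make(a.value[idx], (
        (a, lambda g: scatter(g, idx, a.shape)),
    ))


def scatter(g, idx, shape):
    """Adjoint of ``getitem``: accumulate ``g`` into a zero array of ``shape``."""
    g = _lift(g)
    val = np.zeros(shape, dtype=np.float64)
    if (isinstance(idx, tuple) and len(idx) == 1
            and isinstance(idx[0], np.ndarray) and idx[0].ndim == 1
            and idx[0].dtype.kind in "iu" and idx[0].size):
        # segment-reduce fast path (np.add.at is an order of magnitude
        # slower on wide rows)
        ids = idx[0]
        gval = g.value
        if np.any(np.diff(ids) < 0):
            order = np.argsort(ids, kind="stable")
            ids = ids[order]
            gval = gval[order]
        starts = np.concatenate([[0], np.flatnonzero(np.diff(ids)) + 1])
        val[ids[starts]] = np.add.reduceat(gval, starts, axis=0)
    else:
        np.add.at(val, idx, g.value)
    return _make(val, ((g, lambda h: getitem(h, idx)),))


def gather(a, indices):
    """Row gather along axis 0 with an integer index array."""
    indices = np.asarray(indices, dtype=np.intp)
    return getitem(a, (indices,))


def segment_sum(a, segment_ids, num_segments: int):
    """Sum rows of ``a`` into ``num_segments`` buckets along axis 0."""
    a = _lift(a)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    return scatter(a, (segment_ids,), (num_segments,) + a.shape[1:])


def concatenate(parts: Sequence, axis=0):
    parts = [_lift(p) for p in parts]
    val = np.concatenate([p.value for p in parts], axis=axis)
    offsets = np.cumsum([0] + [p.shape[axis] for p in parts])
    parent_list = []
    for k, p in enumerate(parts):
        sl = [slice(None)] * val.ndim
        sl[axis] = slice(int(offsets[k]), int(offsets[k + 1]))
        sl = tuple(sl)
        parent_list.append((p, lambda g, sl=sl: getitem(g, sl)))
    return _make(val, tuple(parent_list))


def stack(parts: Sequence, axis=0):
    parts = [_lift(p) for p in parts]
    expanded = [reshape(p, p.shape[:axis] + (1,) + p.shape[axis:]) for p in parts]
    return concatenate(expanded, axis=axis)


# ---------------------------------------------------------------------------
# reverse-mode driver
# ---------------------------------------------------------------------------

def _topo_order(root: Tensor) -> list:
    order, seen = [], set()
    stack: list = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if parent.requires and id(parent) not in seen:
                stack.append((parent, False))
    return order


def grad(output: Tensor, inputs: Iterable[Tensor], cotangent=None,
         create_graph: bool = False) -> list:
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    ``cotangent`` seeds the backward pass (defaults to ones, i.e. the plain
    gradient for a scalar output). With ``create_graph=True`` the returned
    gradients are themselves differentiable.
    """
    inputs = list(inputs)
    if not output.requires:
        return [Tensor(np.zeros(x.shape)) for x in inputs]
    if cotangent is None:
        cotangent = Tensor(np.ones(output.shape))
    else:
        cotangent = _lift(cotangent)

    order = _topo_order(output)
    grads: dict = {id(output): cotangent}

    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = bool(create_graph)
    try:
        # Reverse topological order: a node is visited only after all of its
        # children, so its accumulated gradient is complete when read.
        for node in reversed(order):
            g = grads.get(id(node))
            if g is None:
                continue
            for parent, vjp in node.parents:
                contribution = vjp(g)
                existing = grads.get(id(parent))
                grads[id(parent)] = contribution if existing is None \
                    else add(existing, contribution)
    finally:
        _GRAD_ENABLED = prev

    out = []
    for x in inputs:
        g = grads.get(id(x))
        out.append(g if g is not None else Tensor(np.zeros(x.shape)))
    return out
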