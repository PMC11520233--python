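"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports higher-order derivatives: the backward pass of every operation is
itself built out of :class:`Tensor` operations, so gradients of gradients
(needed for the critic gradient penalty) come for free.

Only the operations required by the model are implemented; everything runs
in float64 for reproducibility.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "add",
    "sub",
    "mul",
    "neg",
    "matmul",
    "transpose",
    "reshape",
    "power",
    "exp",
    "log",
    "sqrt",
    "where",
    "tsum",
    "tmean",
    "getitem",
    "concatenate",
    "selu",
    "logsumexp",
    "grad",
]


class Tensor:
    """A numpy array plus the tape needed to differentiate through it."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        vjps: tuple[Callable[["Tensor"], "Tensor"], ...] = (),
    ):
        self.data = np.asarray(data, dtype=np.float64)
        needs = requires_grad or any(p.requires_grad for p in parents)
        self.requires_grad = needs
        # prune dead branches so the graph only tracks differentiable paths
        if needs and parents:
            self._parents = parents
            self._vjps = vjps
        else:
            self._parents = ()
            self._vjps = ()

    # -- conveniences ----------------------------------------------------
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

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return mul(self, power(astensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __pow__(self, n):
        return power(self, n)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- broadcasting helper -------------------------------------------------


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
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


# -- primitive operations ------------------------------------------------


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data + b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(g, a.shape),
            lambda g: _unbroadcast(g, b.shape),
        ),
    )


def neg(a) -> Tensor:
    a = astensor(a)
    return Tensor(-a.data, parents=(a,), vjps=(lambda g: neg(g),))


def sub(a, b) -> Tensor:
    return add(astensor(a), neg(astensor(b)))


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(mul(g, b), a.shape),
            lambda g: _unbroadcast(mul(g, a), b.shape),
        ),
    )


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data @ b.data,
        parents=(a, b),
        vjps=(
            lambda g: matmul(g, transpose(b)),
            lambda g: matmul(transpose(a), g),
        ),
    )


def transpose(a) -> Tensor:
    a = astensor(a)
    return Tensor(a.data.T, parents=(a,), vjps=(lambda g: transpose(g),))


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    old = a.shape
    return Tensor(
        a.data.reshape(shape), parents=(a,), vjps=(lambda g: reshape(g, old),)
    )


def power(a, n: float) -> Tensor:
    a = astensor(a)
    return Tensor(
        a.data**n,
        parents=(a,),
        vjps=(lambda g: mul(g, mul(Tensor(float(n)), power(a, n - 1.0))),),
    )


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = astensor(a)
    # the vjp rebuilds exp(a) so second-order derivatives stay on the tape
    return Tensor(np.exp(a.data), parents=(a,), vjps=(lambda g: mul(g, exp(a)),))


def log(a) -> Tensor:
    a = astensor(a)
    return Tensor(
        np.log(a.data), parents=(a,), vjps=(lambda g: mul(g, power(a, -1.0)),)
    )


def where(cond, a, b) -> Tensor:
    """Select with a *constant* condition (no gradient through ``cond``)."""
    a, b = astensor(a), astensor(b)
    c = np.asarray(cond, dtype=bool)
    return Tensor(
        np.where(c, a.data, b.data),
        parents=(a, b),
        vjps=(
            lambda g: _unbroadcast(mul(g, Tensor(c.astype(np.float64))), a.shape),
            lambda g: _unbroadcast(mul(g, Tensor((~c).astype(np.float64))), b.shape),
        ),
    )


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g: Tensor) -> Tensor:
        gd = g
        if axis is not None and not keepdims:
            kd_shape = list(a.shape)
            axes = (axis,) if np.isscalar(axis) else axis
            for ax in axes:
                kd_shape[ax] = 1
            gd = reshape(gd, tuple(kd_shape))
        return mul(gd, Tensor(np.ones(a.shape)))

    return Tensor(out_data, parents=(a,), vjps=(vjp,))


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in ((axis,) if np.isscalar(axis) else axis)]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / float(n)))


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    shape = a.shape

    def vjp(g: Tensor) -> Tensor:
        return _scatter(g, idx, shape)

    return Tensor(a.data[idx], parents=(a,), vjps=(vjp,))


def _scatter(g: Tensor, idx, shape) -> Tensor:
    """Adjoint of ``getitem``: place ``g`` at ``idx`` in a zero array."""
    g = astensor(g)
    out = np.zeros(shape)
    np.add.at(out, idx, g.data)
    return Tensor(out, parents=(g,), vjps=(lambda gg: getitem(gg, idx),))


def concatenate(tensors: Sequence, axis: int = 0) -> Tensor:
    ts = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        sl = [slice(None)] * ts[i].ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: getitem(g, sl)

    return Tensor(
        np.concatenate([t.data for t in ts], axis=axis),
        parents=tuple(ts),
        vjps=tuple(make_vjp(i) for i in range(len(ts))),
    )


_SELU_ALPHA = 1.6732632423543772848170429916717
_SELU_SCALE = 1.0507009873554804934193349852946


def selu(a) -> Tensor:
    a = astensor(a)
    pos = a.data > 0
    neg_vals = np.minimum(a.data, 0.0)  # keep exp off the positive branch
    data = _SELU_SCALE * np.where(pos, a.data, _SELU_ALPHA * (np.exp(neg_vals) - 1.0))

    def vjp(g: Tensor) -> Tensor:
        # clamp the exp argument on the tape too, or inf * 0 = nan leaks into
        # second-order derivatives through the discarded branch
        neg_part = where(pos, Tensor(np.zeros(a.shape)), a)
        deriv = where(
            pos,
            Tensor(np.full(a.shape, _SELU_SCALE)),
            mul(Tensor(_SELU_SCALE * _SELU_ALPHA), exp(neg_part)),
        )
        return mul(g, deriv)

    return Tensor(data, parents=(a,), vjps=(vjp,))


def logsumexp(a, axis=None, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp built from differentiable primitives."""
    a = astensor(a)
    m = np.max(a.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    shifted = sub(a, Tensor(m))
    s = log(tsum(exp(shifted), axis=axis, keepdims=True))
    out = add(s, Tensor(m))
    if not keepdims and axis is not None:
        out = reshape(out, np.squeeze(out.data, axis=axis).shape)
    elif not keepdims and axis is None:
        out = reshape(out, ())
    return out


# -- backward ------------------------------------------------------------


def _topo_order(root: Tensor) -> list:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, inputs: Sequence[Tensor], seed: Tensor | None = None):
    """Gradients of ``output`` w.r.t. each of ``inputs``.

    The returned tensors stay on the tape, so differentiating through them
    again (double backprop) is valid.
    """
    if not output.requires_grad:
        return [Tensor(np.zeros(x.shape)) for x in inputs]
    if seed is None:
        seed = Tensor(np.ones(output.shape))
    gmap: dict[int, Tensor] = {id(output): seed}
    order = _topo_order(output)
    for node in reversed(order):
        g = gmap.get(id(node))
        if g is None:
            continue
        for parent, vjp in zip(node._parents, node._vjps):
            if not parent.requires_grad:
                continue
            contrib = vjp(g)
            prev = gmap.get(id(parent))
            gmap[id(parent)] = contrib if prev is None else add(prev, contrib)
    return [gmap.get(id(x), Tensor(np.zeros(x.shape))) for x in inputs]
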