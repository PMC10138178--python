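"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine sufficient to train the sequence models in this
package: dense linear maps, batched ``einsum`` contractions (used for the
frequency-domain operators, whose complex parameters are stored as paired
real/imaginary arrays), pointwise nonlinearities, reductions, and an Adam
optimizer.  Everything is ``float64`` and single-threaded NumPy, so a fixed
seed gives bit-reproducible training on a given BLAS backend.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "mul",
    "matmul",
    "einsum",
    "concat",
    "softmax",
    "layer_norm",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus a gradient and the local backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed gradient: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
                continue
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __truediv__(self, other):
        other = _wrap(other)
        return self * power(other, -1.0)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __getitem__(self, key):
        out_data = self.data[key]
        x = self

        def bw(g):
            full = np.zeros_like(x.data)
            np.add.at(full, key, g)
            x._accumulate(full)

        return Tensor(out_data, parents=(x,), backward=bw if x.requires_grad else None)

    def reshape(self, *shape):
        x = self
        out = Tensor(x.data.reshape(*shape), parents=(x,),
                     backward=(lambda g: x._accumulate(g.reshape(x.shape)))
                     if x.requires_grad else None)
        return out

    def transpose(self, *axes):
        x = self
        ax = axes if axes else tuple(reversed(range(x.ndim)))
        inv = np.argsort(ax)
        return Tensor(x.data.transpose(ax), parents=(x,),
                      backward=(lambda g: x._accumulate(g.transpose(inv)))
                      if x.requires_grad else None)

    def sum(self, axis=None, keepdims=False):
        x = self

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            x._accumulate(np.broadcast_to(g, x.shape).copy())

        return Tensor(x.data.sum(axis=axis, keepdims=keepdims), parents=(x,),
                      backward=bw if x.requires_grad else None)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x, requires_grad=False)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


# ------------------------------------------------------------------ primitives
def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor(a.data + b.data, parents=(a, b), backward=bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(a.data * b.data, parents=(a, b), backward=bw)


def power(a: Tensor, p: float) -> Tensor:
    def bw(g):
        a._accumulate(_unbroadcast(g * p * np.power(a.data, p - 1.0), a.shape))

    return Tensor(np.power(a.data, p), parents=(a,),
                  backward=bw if a.requires_grad else None)


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bw(g):
        a._accumulate(g * out_data)

    return Tensor(out_data, parents=(a,), backward=bw if a.requires_grad else None)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bw(g):
        a._accumulate(g * (1.0 - out_data * out_data))

    return Tensor(out_data, parents=(a,), backward=bw if a.requires_grad else None)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=bw if a.requires_grad else None)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g):
        a._accumulate(g * mask)

    return Tensor(a.data * mask, parents=(a,), backward=bw if a.requires_grad else None)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.shape))

    return Tensor(np.matmul(a.data, b.data), parents=(a, b), backward=bw)


def einsum(subscripts: str, *operands: Tensor) -> Tensor:
    """Differentiable einsum.

    Restricted to explicit-output specs where no index repeats within a single
    operand and every operand index appears in the output or another operand —
    which covers all contractions used by the models here.
    """
    ops = [_wrap(o) for o in operands]
    in_spec, out_spec = subscripts.replace(" ", "").split("->")
    in_subs = in_spec.split(",")
    out_data = np.einsum(subscripts, *[o.data for o in ops])

    def bw(g):
        for i, op in enumerate(ops):
            if not op.requires_grad:
                continue
            others = [ops[j].data for j in range(len(ops)) if j != i]
            other_subs = [in_subs[j] for j in range(len(ops)) if j != i]
            spec = ",".join([out_spec] + other_subs) + "->" + in_subs[i]
            op._accumulate(np.einsum(spec, g, *others))

    return Tensor(out_data, parents=tuple(ops), backward=bw)


def concat(tensors, axis: int = 0) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(np.concatenate([t.data for t in ts], axis=axis),
                  parents=tuple(ts), backward=bw)


# ------------------------------------------------------------------ composites
def softmax(a: Tensor, axis: int = -1) -> Tensor:
    # shift by a detached max for numerical stability; softmax and its gradient
    # are invariant to the shift
    shift = constant(a.data.max(axis=axis, keepdims=True))
    e = exp(a - shift)
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis, then apply per-channel gain and bias."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * power(var + constant(eps), -0.5) * gain + bias


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
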