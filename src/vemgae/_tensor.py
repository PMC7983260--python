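"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations needed by the graph autoencoders are provided:
matrix product, elementwise arithmetic, relu/sigmoid/exp/log, full
summation and transposition.  No broadcasting beyond scalar * tensor;
every binary op requires equal shapes, which keeps the backward rules
trivial and the graph cheap to walk.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph bookkeeping -------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep over many layers
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

    # -- operators ---------------------------------------------------------

    def __matmul__(self, other: "Tensor") -> "Tensor":
        return matmul(self, other)

    def __add__(self, other):
        return add(self, as_tensor(other))

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __mul__(self, other):
        if np.isscalar(other):
            return scale(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return scale(self, -1.0)

    @property
    def T(self) -> "Tensor":
        return transpose(self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g @ b.data.T)
        if b.requires_grad or b._parents:
            b._accumulate(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch in add: {a.shape} vs {b.shape}")

    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    return _make(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch in sub: {a.shape} vs {b.shape}")

    def backward(g):
        a._accumulate(g)
        b._accumulate(-g)

    return _make(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch in mul: {a.shape} vs {b.shape}")

    def backward(g):
        a._accumulate(g * b.data)
        b._accumulate(g * a.data)

    return _make(a.data * b.data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    def backward(g):
        a._accumulate(g * c)

    return _make(a.data * c, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable two-sided evaluation
    out_data = np.empty_like(a.data)
    pos = a.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ez = np.exp(a.data[~pos])
    out_data[~pos] = ez / (1.0 + ez)

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the interior."""
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accumulate(g * mask)

    return _make(np.clip(a.data, lo, hi), (a,), backward)


def tsum(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(np.full_like(a.data, float(g)))

    return _make(a.data.sum(), (a,), backward)


def transpose(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g.T)

    return _make(a.data.T, (a,), backward)


def square(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g * 2.0 * a.data)

    return _make(a.data ** 2, (a,), backward)


def dropout(a: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (eval mode) or rate 0."""
    if rng is None or rate <= 0.0:
        return a
    keep = 1.0 - rate
    mask = (rng.random(a.shape) < keep) / keep

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)
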