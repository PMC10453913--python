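"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operator set the network needs: broadcast-aware
arithmetic, (batched) matmul, the usual pointwise nonlinearities,
row-wise and masked softmax, reductions, reshaping/slicing and
concatenation.  Gradients are accumulated by a topological backward
sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "matmul",
    "softmax",
    "masked_softmax",
    "log_softmax",
    "sigmoid",
    "tanh",
    "leaky_relu",
    "elu",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev
        self._backward = _backward

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray, own: bool = False) -> None:
        """Accumulate a gradient contribution.

        ``own=True`` promises `g` is a freshly allocated array no other
        node references, letting us adopt it without copying.
        """
        if self.grad is None:
            if not own or g.base is not None or not g.flags.writeable:
                g = g.copy()
            self.grad = g
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = _unbroadcast(g, self.shape)
                self._accum(ga, own=ga is not g)
            if other.requires_grad:
                gb = _unbroadcast(g, other.shape)
                other._accum(gb, own=gb is not g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g, own=True)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape),
                             own=True)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape), own=True)
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape),
                    own=True,
                )

        out._backward = bw
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple)
            and all(isinstance(i, (int, slice)) for i in idx))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:  # slices never alias, so a direct add suffices
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                self._accum(full, own=True)

        out._backward = bw
        return out

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.shape)
        )
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            np.swapaxes(g, a, b)
        )
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy(), own=True)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def item(self) -> float:
        return float(self.data)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with numpy batching semantics (2-D weights broadcast)."""
    out = Tensor(np.matmul(a.data, b.data), _prev=(a, b))

    def bw(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.shape), own=True)
        if b.requires_grad:
            if b.ndim == 2 and g.ndim > 2:
                # flatten batch dims into one GEMM instead of a batched
                # product followed by a reduction
                gb = a.data.reshape(-1, a.shape[-1]).T \
                    @ g.reshape(-1, g.shape[-1])
            else:
                gb = _unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g),
                                  b.shape)
            b._accum(gb, own=True)

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * s * (1.0 - s), own=True)
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * (1.0 - t * t), own=True)
    return out


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, slope * x.data), _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(
        g * np.where(pos, 1.0, slope), own=True
    )
    return out


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    expm1 = alpha * np.expm1(np.minimum(x.data, 0.0))
    out = Tensor(np.where(pos, x.data, expm1), _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(
        g * np.where(pos, 1.0, expm1 + alpha), own=True
    )
    return out


def _softmax_bw(x: Tensor, y: np.ndarray, axis: int):
    def bw(g):
        if x.requires_grad:
            x._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)), own=True)

    return bw


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _prev=(x,))
    out._backward = _softmax_bw(x, y, axis)
    return out


def masked_softmax(x: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax restricted to entries where `mask` is truthy.

    Every slice along `axis` must contain at least one allowed entry;
    disallowed entries get exactly zero weight and pass no gradient.
    """
    m = mask.astype(bool)
    if not m.any(axis=axis).all():
        raise ValueError("masked_softmax: a slice has no allowed entries")
    neg = np.where(m, x.data, -np.inf)
    z = neg - neg.max(axis=axis, keepdims=True)
    e = np.zeros_like(x.data)
    np.exp(z, out=e, where=m)  # exponentiate allowed entries only
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _prev=(x,))
    out._backward = _softmax_bw(x, y, axis)
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = Tensor(z - lse, _prev=(x,))
    y = np.exp(z - lse)

    def bw(g):
        if x.requires_grad:
            x._accum(g - y * g.sum(axis=axis, keepdims=True), own=True)

    out._backward = bw
    return out
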