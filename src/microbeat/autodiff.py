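"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-free define-by-run graph: each :class:`Tensor` remembers its parents
and a closure that routes the output gradient back to them.  Only the
operations the recurrent extractor, the mini-classifiers and their losses
need are implemented (elementwise arithmetic, 2-D matmul, tanh / sigmoid /
softplus / exp / log, powers, reductions, reshape, slicing, concatenation).
Everything is float64; gradients are accumulated, never overwritten.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _bw: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._bw = _bw

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _op(data, parents: tuple["Tensor", ...], bw) -> "Tensor":
        if any(p.requires_grad for p in parents):
            return Tensor(data, True, parents, bw)
        return Tensor(data)

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self._accum(np.ones_like(self.data) if grad is None else grad)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- convenience -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._op(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._op(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._op(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._op(out_data, (self,), bw)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._op(out_data, (self, other), bw)

    def t(self):
        """2-D transpose."""
        def bw(g):
            self._accum(g.T)

        return Tensor._op(self.data.T, (self,), bw)

    # -- nonlinearities ----------------------------------------------------

    def tanh(self):
        t = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - t * t))

        return Tensor._op(t, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._op(s, (self,), bw)

    def softplus(self):
        # log(1 + e^x), overflow-safe; derivative is sigmoid(x)
        x = self.data
        out_data = np.logaddexp(0.0, x)

        def bw(g):
            self._accum(g / (1.0 + np.exp(-np.clip(x, -500, 500))))

        return Tensor._op(out_data, (self,), bw)

    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            self._accum(g * e)

        return Tensor._op(e, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._op(np.log(self.data), (self,), bw)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._op(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._op(self.data.reshape(*shape), (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            gp = np.zeros_like(self.data)
            np.add.at(gp, idx, g)
            self._accum(gp)

        return Tensor._op(out_data, (self,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient back."""
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor._op(out_data, tuple(tensors), bw)


class Adam:
    """Adaptive-moment optimizer over a list of leaf Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
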