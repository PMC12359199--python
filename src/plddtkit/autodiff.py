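"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the equivariant message-passing head
needs: dense affine maps, SiLU/ReLU nonlinearities, row gather / segment
sum (the scatter pattern of message passing), elementwise arithmetic with
broadcasting, row-wise log-softmax and per-row column picks for the
cross-entropy loss.  Gradients are float64 throughout and are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() needs a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        a, b = self, Tensor._wrap(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division only by python/numpy constants")
        return self * (1.0 / other)

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, Tensor._wrap(other)

        def bw(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), bw)

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def silu(self):
        a = self
        sig = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * (sig * (1.0 + a.data * (1.0 - sig))))

        return Tensor._make(a.data * sig, (a,), bw)

    def maximum(self, const: float):
        """Elementwise max with a constant (used to clamp log-probabilities)."""
        a = self
        mask = a.data > const

        def bw(g):
            a._accum(g * mask)

        return Tensor._make(np.maximum(a.data, const), (a,), bw)

    # -- reductions & reshaping ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def concat(self, others, axis=1):
        parts = [self] + [Tensor._wrap(o) for o in others]
        sizes = [p.data.shape[axis] for p in parts]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
                if p.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    p._accum(g[tuple(sl)])

        return Tensor._make(
            np.concatenate([p.data for p in parts], axis=axis), parts, bw
        )

    # -- gather / scatter -------------------------------------------------
    def gather_rows(self, idx: np.ndarray):
        a = self
        idx = np.asarray(idx, dtype=int)

        def bw(g):
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            a._accum(acc)

        return Tensor._make(a.data[idx], (a,), bw)

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int):
        """Sum rows into ``num_segments`` buckets (message aggregation)."""
        a = self
        seg = np.asarray(segment_ids, dtype=int)
        out = np.zeros((num_segments,) + a.data.shape[1:])
        np.add.at(out, seg, a.data)

        def bw(g):
            a._accum(g[seg])

        return Tensor._make(out, (a,), bw)

    def take_per_row(self, cols: np.ndarray):
        """Pick element ``cols[i]`` from row i; returns shape (N,)."""
        a = self
        cols = np.asarray(cols, dtype=int)
        rows = np.arange(a.data.shape[0])

        def bw(g):
            acc = np.zeros_like(a.data)
            acc[rows, cols] = g
            a._accum(acc)

        return Tensor._make(a.data[rows, cols], (a,), bw)

    def log_softmax(self):
        """Row-wise log-softmax for a 2-D tensor."""
        a = self
        m = a.data.max(axis=1, keepdims=True)
        z = a.data - m
        lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
        out = z - lse
        p = np.exp(out)

        def bw(g):
            a._accum(g - p * g.sum(axis=1, keepdims=True))

        return Tensor._make(out, (a,), bw)


def linear(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    return x @ W + b


class Adam:
    """Plain Adam over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
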