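"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the paired-chain CNN and the reciprocal
attention model need: broadcasting add/mul, batched matmul, slicing,
concatenation, reshape/transpose, ReLU/sigmoid/log, masked softmax,
embedding lookup, 1-D max pooling and axis reductions, plus an Adam
optimizer.  All randomness (init, dropout, batch order) is owned by the
caller through explicit ``numpy.random.Generator`` instances, so training
is reproducible bit-for-bit on a fixed platform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
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
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    __matmul__ = matmul

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, *axes) -> "Tensor":
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))

        out._backward = bw
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        out._backward = bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))

        out._backward = bw
        return out

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / self.data.size)

    # ------------------------------------------------------------ nonlinear
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def maxpool1d(self, k: int = 2) -> "Tensor":
        """Non-overlapping max pooling along the last axis (floor division)."""
        n = self.data.shape[-1] // k
        trimmed = self.data[..., : n * k]
        blocks = trimmed.reshape(*self.data.shape[:-1], n, k)
        arg = blocks.argmax(axis=-1)
        out = Tensor(blocks.max(axis=-1), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            gb = np.zeros_like(blocks)
            np.put_along_axis(gb, arg[..., None], g[..., None], axis=-1)
            full = np.zeros_like(self.data)
            full[..., : n * k] = gb.reshape(*self.data.shape[:-1], n * k)
            self._accumulate(full)

        out._backward = bw
        return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------- functional


def concat(tensors: list, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    out._backward = bw
    return out


def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``table[indices]`` with scatter-add gradient."""
    idx = np.asarray(indices)
    out = Tensor(table.data[idx], parents=(table,))

    def bw(g):
        if table.requires_grad:
            full = np.zeros_like(table.data)
            np.add.at(full, idx.reshape(-1), g.reshape(-1, table.data.shape[-1]))
            table._accumulate(full)

    out._backward = bw
    return out


def masked_softmax(scores: Tensor, key_mask: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to positions where key_mask == 1.

    Masked positions receive exactly zero probability; each row over valid
    keys sums to one.  ``key_mask`` broadcasts against ``scores``.
    """
    m = np.broadcast_to(np.asarray(key_mask, dtype=bool), scores.data.shape)
    if not m.any(axis=-1).all():
        raise ValueError("masked_softmax: a row has no valid key positions")
    x = np.where(m, scores.data, -np.inf)
    x = x - x.max(axis=-1, keepdims=True)
    e = np.where(m, np.exp(x), 0.0)
    p = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(p, parents=(scores,))

    def bw(g):
        if scores.requires_grad:
            dot = (g * p).sum(axis=-1, keepdims=True)
            scores._accumulate(p * (g - dot))

    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (evaluation mode) or p == 0."""
    if rng is None or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


def bce_loss(prob: Tensor, labels: np.ndarray, eps: float = 1e-9) -> Tensor:
    """Mean binary cross-entropy between predicted probabilities and 0/1 labels."""
    y = np.asarray(labels, dtype=np.float64)
    p = prob * (1.0 - 2.0 * eps) + eps  # keep log() finite
    loss = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())
    return loss.mean()


class Adam:
    """Adam optimizer (Kingma & Ba) over a fixed parameter list."""

    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
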