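"""Minimal reverse-mode automatic differentiation over numpy arrays.

The graph attention model needs gradients for a handful of dense
operations (matrix products, masked row-softmax, ReLU, row gather/scatter,
convex view fusion, binary cross-entropy). This module provides exactly
those as composable :class:`Tensor` operations with hand-written adjoints,
plus an Adam optimizer. Everything is deterministic given the input
arrays; no global state.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "matmul",
    "matmul_t",
    "add",
    "relu",
    "gather_rows",
    "replace_rows",
    "add_rows",
    "scale",
    "cols",
    "concat_cols",
    "masked_softmax",
    "fuse_weighted",
    "bce_with_logits",
    "softmax",
    "sigmoid",
    "Adam",
]


class Tensor:
    """A numpy array plus the closure that back-propagates into its parents."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data)
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topological sort; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


def constant(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def backward(g: np.ndarray) -> None:
        a.accumulate(g @ b.data.T)
        b.accumulate(a.data.T @ g)

    out._backward = backward
    return out


def matmul_t(a: Tensor, b: Tensor) -> Tensor:
    """a @ b.T without materializing a transposed tensor node."""
    out = Tensor(a.data @ b.data.T, (a, b))

    def backward(g: np.ndarray) -> None:
        a.accumulate(g @ b.data)
        b.accumulate(g.T @ a.data)

    out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def backward(g: np.ndarray) -> None:
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0), (x,))

    def backward(g: np.ndarray) -> None:
        x.accumulate(g * (x.data > 0))

    out._backward = backward
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)
    out = Tensor(x.data[idx], (x,))

    def backward(g: np.ndarray) -> None:
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        x.accumulate(gx)

    out._backward = backward
    return out


def replace_rows(base: Tensor, idx: np.ndarray, repl: Tensor) -> Tensor:
    """Copy of ``base`` with rows ``idx`` replaced by ``repl``."""
    idx = np.asarray(idx)
    data = base.data.copy()
    data[idx] = repl.data
    out = Tensor(data, (base, repl))

    def backward(g: np.ndarray) -> None:
        gb = g.copy()
        gb[idx] = 0
        base.accumulate(gb)
        repl.accumulate(g[idx])

    out._backward = backward
    return out


def add_rows(base: Tensor, idx: np.ndarray, addend: Tensor) -> Tensor:
    """Copy of ``base`` with ``addend`` added to rows ``idx`` (idx unique)."""
    idx = np.asarray(idx)
    data = base.data.copy()
    data[idx] += addend.data
    out = Tensor(data, (base, addend))

    def backward(g: np.ndarray) -> None:
        base.accumulate(g)
        addend.accumulate(g[idx])

    out._backward = backward
    return out


def scale(x: Tensor, s: float) -> Tensor:
    out = Tensor(x.data * s, (x,))

    def backward(g: np.ndarray) -> None:
        x.accumulate(g * s)

    out._backward = backward
    return out


def cols(x: Tensor, start: int, stop: int) -> Tensor:
    out = Tensor(x.data[:, start:stop], (x,))

    def backward(g: np.ndarray) -> None:
        gx = np.zeros_like(x.data)
        gx[:, start:stop] = g
        x.accumulate(gx)

    out._backward = backward
    return out


def concat_cols(parts: Sequence[Tensor]) -> Tensor:
    parts = list(parts)
    out = Tensor(np.concatenate([p.data for p in parts], axis=1), parts)
    widths = [p.data.shape[1] for p in parts]

    def backward(g: np.ndarray) -> None:
        off = 0
        for p, w in zip(parts, widths):
            p.accumulate(g[:, off : off + w])
            off += w

    out._backward = backward
    return out


def masked_softmax(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to entries where ``mask`` is True.

    Every row must contain at least one True entry (the model guarantees
    this by always including a node in its own neighborhood).
    """
    mask = np.asarray(mask, dtype=bool)
    neg = np.where(mask, logits.data, -np.inf)
    mx = neg.max(axis=1, keepdims=True)
    ex = np.exp(neg - mx)
    ex[~mask] = 0.0
    denom = ex.sum(axis=1, keepdims=True)
    a = ex / denom
    out = Tensor(a, (logits,))

    def backward(g: np.ndarray) -> None:
        dot = (g * a).sum(axis=1, keepdims=True)
        logits.accumulate(a * (g - dot))

    out._backward = backward
    return out


def fuse_weighted(hs: Sequence[Tensor], logits: Tensor) -> Tensor:
    """Convex combination sum_i softmax(logits)_i * hs[i] (view fusion)."""
    hs = list(hs)
    w = logits.data - logits.data.max()
    alpha = np.exp(w)
    alpha /= alpha.sum()
    z = sum(alpha[i] * hs[i].data for i in range(len(hs)))
    out = Tensor(z, list(hs) + [logits])

    def backward(g: np.ndarray) -> None:
        dalpha = np.empty_like(alpha)
        for i, h in enumerate(hs):
            h.accumulate(alpha[i] * g)
            dalpha[i] = float((g * h.data).sum())
        dlog = alpha * (dalpha - float((alpha * dalpha).sum()))
        logits.accumulate(dlog)

    out._backward = backward
    return out


def fusion_weights(logits: np.ndarray) -> np.ndarray:
    """softmax of fusion logits (forward-only convenience)."""
    w = np.asarray(logits, dtype=float)
    w = w - w.max()
    a = np.exp(w)
    return a / a.sum()


def softmax(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    m = x.max()
    e = np.exp(x - m)
    return e / e.sum()


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(np.asarray(x, dtype=float))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from raw logits (numerically stable)."""
    y = np.asarray(labels, dtype=logits.data.dtype)
    x = logits.data
    # log(1+exp(-|x|)) + max(x,0) - x*y
    loss = np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(np.asarray(loss.mean(), dtype=x.dtype), (logits,))

    def backward(g: np.ndarray) -> None:
        p = sigmoid(x)
        logits.accumulate(g * (p - y) / x.size)

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype, copy=False
            )
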