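"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ndarray and a
closure that propagates gradients to its parents.  Only the operations needed
by the relation-extraction networks are provided (affine maps, elementwise
nonlinearities, concatenation, time-axis slicing, max pooling, embedding
lookup and the two loss heads).  Graphs are built eagerly by calling the free
functions below; ``backward()`` on a scalar runs a topological sweep.

All arrays are float64.  Shapes follow the (batch, time, features) convention
used throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "mul", "affine", "concat", "sigmoid", "tanh", "relu",
    "softmax", "select_time", "assemble_time", "slice_last", "max_over_time",
    "embedding_lookup", "dropout_mask", "mse_loss", "sigmoid_bce_loss",
    "add_scalar",
]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None,
                 name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Accumulate gradients of this (scalar) tensor w.r.t. all ancestors."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be thousands of nodes deep
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
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self.name!r})"


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def add_scalar(a, c):
    a = _wrap(a)
    out = Tensor(a.data + c, parents=(a,))
    out._backward = lambda g: a.accumulate(g)
    return out


def mul(a, b):
    """Elementwise (broadcasting) product; either side may be a plain array."""
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def affine(x, w, b=None):
    """``x @ w (+ b)`` over the last axis of ``x``; any leading dims."""
    x, w = _wrap(x), _wrap(w)
    lead = x.data.shape[:-1]
    x2 = x.data.reshape(-1, x.data.shape[-1])
    y = x2 @ w.data
    if b is not None:
        b = _wrap(b)
        y = y + b.data
        parents = (x, w, b)
    else:
        parents = (x, w)
    out = Tensor(y.reshape(*lead, w.data.shape[-1]), parents=parents)

    def bw(g):
        g2 = g.reshape(-1, g.shape[-1])
        if x.requires_grad:
            x.accumulate((g2 @ w.data.T).reshape(x.data.shape))
        if w.requires_grad:
            w.accumulate(x2.T @ g2)
        if b is not None and b.requires_grad:
            b.accumulate(g2.sum(axis=0))

    out._backward = bw
    return out


def concat(tensors, axis=-1):
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t.accumulate(g[tuple(idx)])

    out._backward = bw
    return out


def slice_last(x, lo, hi):
    x = _wrap(x)
    out = Tensor(x.data[..., lo:hi], parents=(x,))

    def bw(g):
        full = np.zeros_like(x.data)
        full[..., lo:hi] = g
        x.accumulate(full)

    out._backward = bw
    return out


def sigmoid(x):
    x = _wrap(x)
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: x.accumulate(g * y * (1.0 - y))
    return out


def tanh(x):
    x = _wrap(x)
    y = np.tanh(x.data)
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: x.accumulate(g * (1.0 - y * y))
    return out


def relu(x):
    x = _wrap(x)
    y = np.maximum(x.data, 0.0)
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: x.accumulate(g * (x.data > 0))
    return out


def softmax(x):
    """Softmax over the last axis, with the exact Jacobian in backward."""
    x = _wrap(x)
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bw(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        x.accumulate(y * (g - dot))

    out._backward = bw
    return out


def select_time(x, t):
    """Pick timestep ``t`` from a (B, T, D) tensor -> (B, D)."""
    x = _wrap(x)
    out = Tensor(x.data[:, t, :], parents=(x,))

    def bw(g):
        full = np.zeros_like(x.data)
        full[:, t, :] = g
        x.accumulate(full)

    out._backward = bw
    return out


def assemble_time(steps):
    """Stack a list of (B, D) tensors into (B, T, D)."""
    steps = [_wrap(s) for s in steps]
    out = Tensor(np.stack([s.data for s in steps], axis=1), parents=tuple(steps))

    def bw(g):
        for t, s in enumerate(steps):
            if s.requires_grad:
                s.accumulate(g[:, t, :])

    out._backward = bw
    return out


def max_over_time(x):
    """Per-feature max over the time axis of (B, T, D) -> (B, D)."""
    x = _wrap(x)
    arg = x.data.argmax(axis=1)  # (B, D)
    out = Tensor(x.data.max(axis=1), parents=(x,))

    def bw(g):
        full = np.zeros_like(x.data)
        b_idx = np.arange(x.data.shape[0])[:, None]
        d_idx = np.arange(x.data.shape[2])[None, :]
        np.add.at(full, (b_idx, arg, d_idx), g)
        x.accumulate(full)

    out._backward = bw
    return out


def embedding_lookup(table, indices):
    """Gather rows of a (V, D) table by an integer (B, T) index array."""
    table = _wrap(table)
    indices = np.asarray(indices, dtype=np.intp)
    out = Tensor(table.data[indices], parents=(table,))

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, indices.ravel(), g.reshape(-1, g.shape[-1]))
        table.accumulate(full)

    out._backward = bw
    return out


def dropout_mask(shape, rate, rng):
    """Inverted-dropout mask: zeros with probability ``rate``, else 1/(1-rate)."""
    if rate <= 0.0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


def mse_loss(pred, target):
    """Mean squared error over all elements (matches mean-over-axes reduction)."""
    pred = _wrap(pred)
    target = np.asarray(target, dtype=np.float64)
    diff = pred.data - target
    out = Tensor(np.mean(diff ** 2), parents=(pred,))
    out._backward = lambda g: pred.accumulate(g * 2.0 * diff / diff.size)
    return out


def sigmoid_bce_loss(logits, targets, mask):
    """Masked binary cross-entropy on logits (fused with the sigmoid).

    ``targets`` and ``mask`` are plain arrays broadcastable to ``logits``;
    positions with mask 0 contribute nothing.  Returns the mean over unmasked
    positions (or 0 if the mask is empty).
    """
    logits = _wrap(logits)
    targets = np.asarray(targets, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    z = logits.data
    # log(1+exp(-|z|)) + max(z,0) - z*y, the stable form of BCE-with-logits
    per = np.maximum(z, 0.0) - z * targets + np.log1p(np.exp(-np.abs(z)))
    denom = mask.sum()
    val = (per * mask).sum() / denom if denom > 0 else 0.0
    out = Tensor(val, parents=(logits,))

    def bw(g):
        if denom > 0:
            p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits.accumulate(g * mask * (p - targets) / denom)

    out._backward = bw
    return out
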