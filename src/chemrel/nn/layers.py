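"""Neural layers built on the autodiff engine.

Conventions match the usual recurrent-toolkit defaults: LSTMs use the
i, f, c, o gate order, glorot-uniform input kernels, orthogonal recurrent
kernels and a forget-gate bias of one; dropout masks are sampled once per
sequence and reused at every timestep (the standard "variational" treatment
of dropout and recurrent_dropout on recurrent layers).
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["glorot_uniform", "orthogonal", "Dense", "Conv1D", "LSTM", "RMSProp"]


def glorot_uniform(rng, shape):
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng, shape):
    """Orthogonal init for recurrent kernels; columns are orthonormal blocks."""
    rows, cols = shape
    blocks = []
    for _ in range(int(np.ceil(cols / rows))):
        q, r = np.linalg.qr(rng.standard_normal((rows, rows)))
        q = q * np.sign(np.diag(r))
        blocks.append(q)
    return np.concatenate(blocks, axis=1)[:, :cols]


class Dense:
    """Affine map over the last axis with an optional activation."""

    def __init__(self, in_dim, units, activation=None, *, rng):
        self.w = Tensor(glorot_uniform(rng, (in_dim, units)), requires_grad=True,
                        name="dense.w")
        self.b = Tensor(np.zeros(units), requires_grad=True, name="dense.b")
        self.activation = activation
        self.units = units

    def __call__(self, x):
        y = ag.affine(x, self.w, self.b)
        if self.activation is not None:
            y = self.activation(y)
        return y

    @property
    def params(self):
        return [self.w, self.b]


class Conv1D:
    """1-D convolution over the time axis with 'same' zero padding.

    Implemented as an affine map over a window of stacked neighbouring
    timesteps, so its per-position outputs align with the recurrent layers
    they are concatenated with.
    """

    def __init__(self, in_dim, filters, width=3, activation=ag.relu, *, rng):
        if width % 2 != 1:
            raise ValueError("conv width must be odd for same padding")
        self.width = width
        self.in_dim = in_dim
        self.filters = filters
        self.w = Tensor(glorot_uniform(rng, (width * in_dim, filters)),
                        requires_grad=True, name="conv.w")
        self.b = Tensor(np.zeros(filters), requires_grad=True, name="conv.b")
        self.activation = activation

    def __call__(self, x):
        """``x``: plain (B, T, C) array or Tensor -> (B, T, filters)."""
        data = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
        b, t, c = data.shape
        half = self.width // 2
        padded = np.zeros((b, t + 2 * half, c))
        padded[:, half:half + t, :] = data
        windows = np.concatenate(
            [padded[:, k:k + t, :] for k in range(self.width)], axis=-1)
        # feature inputs carry no gradient, so windows enter as a constant
        y = ag.affine(Tensor(windows), self.w, self.b)
        if self.activation is not None:
            y = self.activation(y)
        return y

    @property
    def params(self):
        return [self.w, self.b]


class LSTM:
    """Single-direction LSTM returning the full per-position sequence.

    ``go_backwards`` processes the sequence right-to-left and re-reverses the
    outputs, so position t always lines up with input position t; a backward
    layer's output at t then summarises the context at and to the right of t.
    """

    def __init__(self, in_dim, units, *, rng):
        self.in_dim = in_dim
        self.units = units
        self.w = Tensor(glorot_uniform(rng, (in_dim, 4 * units)),
                        requires_grad=True, name="lstm.w")
        self.u = Tensor(orthogonal(rng, (units, 4 * units)),
                        requires_grad=True, name="lstm.u")
        bias = np.zeros(4 * units)
        bias[units:2 * units] = 1.0  # forget-gate bias
        self.b = Tensor(bias, requires_grad=True, name="lstm.b")

    @property
    def params(self):
        return [self.w, self.u, self.b]

    @property
    def n_params(self):
        return 4 * ((self.in_dim + self.units) * self.units + self.units)

    def __call__(self, x, *, go_backwards=False, dropout=0.0,
                 recurrent_dropout=0.0, train=False, rng=None):
        batch, t_len, _ = x.data.shape if isinstance(x, Tensor) else x.shape
        u_ = self.units
        if train and (dropout > 0 or recurrent_dropout > 0):
            if rng is None:
                raise ValueError("training with dropout requires an rng")
            in_mask = ag.dropout_mask((batch, self.in_dim), dropout, rng)
            rec_mask = ag.dropout_mask((batch, u_), recurrent_dropout, rng)
        else:
            in_mask = rec_mask = None

        h = Tensor(np.zeros((batch, u_)))
        c = Tensor(np.zeros((batch, u_)))
        order = range(t_len - 1, -1, -1) if go_backwards else range(t_len)
        outputs = [None] * t_len
        for t in order:
            x_t = ag.select_time(x, t)
            if in_mask is not None:
                x_t = ag.mul(x_t, in_mask)
            h_in = ag.mul(h, rec_mask) if rec_mask is not None else h
            z = ag.add(ag.affine(x_t, self.w, self.b), ag.affine(h_in, self.u))
            i = ag.sigmoid(ag.slice_last(z, 0, u_))
            f = ag.sigmoid(ag.slice_last(z, u_, 2 * u_))
            g = ag.tanh(ag.slice_last(z, 2 * u_, 3 * u_))
            o = ag.sigmoid(ag.slice_last(z, 3 * u_, 4 * u_))
            c = ag.add(ag.mul(f, c), ag.mul(i, g))
            h = ag.mul(o, ag.tanh(c))
            outputs[t] = h
        return ag.assemble_time(outputs)


class RMSProp:
    """RMSProp with the standard accumulator update and no momentum."""

    def __init__(self, params, lr=0.001, rho=0.9, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, s in zip(self.params, self.cache):
            if p.grad is None:
                continue
            s *= self.rho
            s += (1.0 - self.rho) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)
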