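"""The pre-training and recognition networks over shared layers.

Two networks share an embedding table ``e1`` and two 300-unit LSTMs: ``l1``
reads the token sequence left-to-right, ``l2`` right-to-left (outputs
re-aligned position-for-position, so ``l2`` at t summarises the context to
the right of t).  Sharing is by identity — the same parameter tensors sit in
both graphs, so a phase-1 update is immediately visible to the recognition
network.

Pre-training network (per position): the original sequence feeds e1/l1/l2;
the substituted sequence, shifted right (i2) and left (i3), feeds two more
applications of the same embedding table.  ``concat(l1, e2)`` -> 300-unit
relu -> 1-unit sigmoid asks "is the token plausible given its left
context?"; a mirrored head does the same against the right context.  Loss is
masked binary cross-entropy, averaged over the two heads.

Recognition network: e1/l1/l2 over the masked candidate window, width-3
relu convolutions over the 10-bit all-entity features (48 filters) and the
2-bit candidate-pair features (6 filters), everything concatenated
(300+300+48+6 = 652 at defaults), a bidirectional LSTM (128 units per
direction), a per-feature max over positions and a 6-way softmax trained
with mean squared error against the one-hot label.  Both networks use
RMSProp; LSTMs use dropout and recurrent dropout of 0.5 (training only).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .candidates import (CandidateBatch, N_CONTEXT_FEATURES, N_PAIR_FEATURES,
                         batch_instances)
from .nn import LSTM, Conv1D, Dense, RMSProp, Tensor
from .nn import autograd as ag
from .pretrain import LengthBatch

__all__ = ["ModelConfig", "SharedLayers", "PretrainingNetwork",
           "RecognitionNetwork", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimiser settings; defaults are the full-scale ones."""

    emb_dim: int = 300
    shared_lstm_units: int = 300
    pretrain_dense_units: int = 300
    i4_conv_filters: int = 48
    i5_conv_filters: int = 6
    conv_width: int = 3
    l3_units_per_direction: int = 128
    l3_conv: bool = False          # optional variant: width-3 conv instead of l3
    dropout: float = 0.5
    recurrent_dropout: float = 0.5
    learning_rate: float = 0.001
    n_classes: int = 6

    def __post_init__(self):
        for name in ("emb_dim", "shared_lstm_units", "pretrain_dense_units",
                     "i4_conv_filters", "i5_conv_filters", "conv_width",
                     "l3_units_per_direction", "learning_rate", "n_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def scaled(cls, emb_dim=24, shared_lstm_units=24,
               l3_units_per_direction=16, **kw) -> "ModelConfig":
        """Desk-scale configuration preserving the layer topology."""
        return cls(emb_dim=emb_dim, shared_lstm_units=shared_lstm_units,
                   pretrain_dense_units=shared_lstm_units,
                   l3_units_per_direction=l3_units_per_direction, **kw)

    def with_overrides(self, **kw) -> "ModelConfig":
        return replace(self, **kw)

    def to_dict(self):
        return asdict(self)


class SharedLayers:
    """Embedding table e1 and the two shared LSTMs l1 (forward), l2 (backward)."""

    def __init__(self, cfg: ModelConfig, vocab_size: int,
                 rng: np.random.Generator,
                 embedding_init: np.ndarray | None = None):
        self.cfg = cfg
        if embedding_init is not None:
            if embedding_init.shape != (vocab_size, cfg.emb_dim):
                raise ValueError(
                    f"embedding init shape {embedding_init.shape} != "
                    f"({vocab_size}, {cfg.emb_dim})")
            emb = np.array(embedding_init, dtype=np.float64)
        else:
            emb = rng.uniform(-0.05, 0.05, size=(vocab_size, cfg.emb_dim))
        self.embedding = Tensor(emb, requires_grad=True, name="e1")
        self.lstm_fwd = LSTM(cfg.emb_dim, cfg.shared_lstm_units, rng=rng)
        self.lstm_bwd = LSTM(cfg.emb_dim, cfg.shared_lstm_units, rng=rng)

    @property
    def params(self):
        return [self.embedding] + self.lstm_fwd.params + self.lstm_bwd.params

    def encode(self, token_ids, *, train=False, rng=None):
        """e1/l1/l2 over a (B, T) id array -> (embedded, l1_seq, l2_seq)."""
        cfg = self.cfg
        e1 = ag.embedding_lookup(self.embedding, token_ids)
        kw = dict(dropout=cfg.dropout, recurrent_dropout=cfg.recurrent_dropout,
                  train=train, rng=rng)
        l1 = self.lstm_fwd(e1, **kw)
        l2 = self.lstm_bwd(e1, go_backwards=True, **kw)
        return e1, l1, l2


class PretrainingNetwork:
    """Negative-sample discrimination network (phase 1)."""

    def __init__(self, cfg: ModelConfig, shared: SharedLayers,
                 rng: np.random.Generator):
        if shared.cfg.emb_dim != cfg.emb_dim:
            raise ValueError("shared layers built with a different config")
        self.cfg = cfg
        self.shared = shared
        width = cfg.shared_lstm_units + cfg.emb_dim
        self.d1 = Dense(width, cfg.pretrain_dense_units, ag.relu, rng=rng)
        self.d2 = Dense(cfg.pretrain_dense_units, 1, None, rng=rng)  # logits
        self.d3 = Dense(width, cfg.pretrain_dense_units, ag.relu, rng=rng)
        self.d4 = Dense(cfg.pretrain_dense_units, 1, None, rng=rng)
        self.optimizer = RMSProp(self.params, lr=cfg.learning_rate)

    @property
    def params(self):
        return (self.shared.params + self.d1.params + self.d2.params
                + self.d3.params + self.d4.params)

    def forward(self, batch: LengthBatch, *, train=False, rng=None):
        """Returns (loss, left logits, right logits, c1 tensor)."""
        _, l1, l2 = self.shared.encode(batch.i1, train=train, rng=rng)
        e2 = ag.embedding_lookup(self.shared.embedding, batch.i2)
        e3 = ag.embedding_lookup(self.shared.embedding, batch.i3)
        c1 = ag.concat([l1, e2])
        c2 = ag.concat([l2, e3])
        z_left = self.d2(self.d1(c1))    # (B, T, 1) logits
        z_right = self.d4(self.d3(c2))
        loss_l = ag.sigmoid_bce_loss(z_left, batch.y_left[..., None],
                                     batch.mask_left[..., None])
        loss_r = ag.sigmoid_bce_loss(z_right, batch.y_right[..., None],
                                     batch.mask_right[..., None])
        loss = ag.mul(ag.add(loss_l, loss_r), 0.5)
        return loss, z_left, z_right, c1

    def train_step(self, batch: LengthBatch, rng: np.random.Generator) -> float:
        self.optimizer.zero_grad()
        loss, _, _, _ = self.forward(batch, train=True, rng=rng)
        loss.backward()
        self.optimizer.step()
        return float(loss.data)

    def predict(self, batch: LengthBatch):
        """Per-position probabilities that each shifted token is original."""
        _, z_left, z_right, _ = self.forward(batch, train=False)
        sig = lambda z: 1.0 / (1.0 + np.exp(-z.data[..., 0]))
        return sig(z_left), sig(z_right)

    def discrimination_accuracy(self, batches) -> float:
        """Masked accuracy of the 0.5-thresholded outputs over both heads."""
        correct = total = 0.0
        for b in batches:
            p_left, p_right = self.predict(b)
            for p, y, m in ((p_left, b.y_left, b.mask_left),
                            (p_right, b.y_right, b.mask_right)):
                correct += (((p > 0.5) == (y > 0.5)) * m).sum()
                total += m.sum()
        return correct / total if total else 0.0


class RecognitionNetwork:
    """Relation classifier over masked candidate windows (phase 2)."""

    def __init__(self, cfg: ModelConfig, shared: SharedLayers,
                 rng: np.random.Generator):
        if shared.cfg.emb_dim != cfg.emb_dim:
            raise ValueError("shared layers built with a different config")
        self.cfg = cfg
        self.shared = shared
        self.v1 = Conv1D(N_CONTEXT_FEATURES, cfg.i4_conv_filters,
                         cfg.conv_width, ag.relu, rng=rng)
        self.v2 = Conv1D(N_PAIR_FEATURES, cfg.i5_conv_filters,
                         cfg.conv_width, ag.relu, rng=rng)
        c3_width = 2 * cfg.shared_lstm_units + cfg.i4_conv_filters + cfg.i5_conv_filters
        if cfg.l3_conv:
            self.l3_conv = Conv1D(c3_width, 2 * cfg.l3_units_per_direction,
                                  cfg.conv_width, ag.relu, rng=rng)
            self.l3_fwd = self.l3_bwd = None
            pooled = 2 * cfg.l3_units_per_direction
        else:
            self.l3_fwd = LSTM(c3_width, cfg.l3_units_per_direction, rng=rng)
            self.l3_bwd = LSTM(c3_width, cfg.l3_units_per_direction, rng=rng)
            self.l3_conv = None
            pooled = 2 * cfg.l3_units_per_direction
        self.d5 = Dense(pooled, cfg.n_classes, ag.softmax, rng=rng)
        self.optimizer = RMSProp(self.params, lr=cfg.learning_rate)

    @property
    def params(self):
        own = self.v1.params + self.v2.params + self.d5.params
        if self.l3_conv is not None:
            own += self.l3_conv.params
        else:
            own += self.l3_fwd.params + self.l3_bwd.params
        return self.shared.params + own

    def forward(self, batch: CandidateBatch, *, train=False, rng=None):
        """Returns (scores (B,6) tensor, aux dict of layer output tensors)."""
        cfg = self.cfg
        _, l1, l2 = self.shared.encode(batch.token_ids, train=train, rng=rng)
        v1 = self.v1(batch.context_features)
        v2 = self.v2(batch.pair_features)
        c3 = ag.concat([l1, l2, v1, v2])
        if self.l3_conv is not None:
            l3 = self.l3_conv(c3)
        else:
            kw = dict(dropout=cfg.dropout,
                      recurrent_dropout=cfg.recurrent_dropout,
                      train=train, rng=rng)
            l3 = ag.concat([self.l3_fwd(c3, **kw),
                            self.l3_bwd(c3, go_backwards=True, **kw)])
        p1 = ag.max_over_time(l3)
        scores = self.d5(p1)
        return scores, {"c3": c3, "l3": l3, "p1": p1}

    def train_step(self, batch: CandidateBatch, rng: np.random.Generator) -> float:
        self.optimizer.zero_grad()
        scores, _ = self.forward(batch, train=True, rng=rng)
        onehot = np.eye(self.cfg.n_classes)[batch.labels]
        loss = ag.mse_loss(scores, onehot)
        loss.backward()
        self.optimizer.step()
        return float(loss.data)

    def predict(self, batch: CandidateBatch) -> np.ndarray:
        """(B, 6) softmax score vectors; deterministic (dropout off)."""
        scores, _ = self.forward(batch, train=False)
        return scores.data

    def predict_instances(self, instances, batch_size: int = 32) -> np.ndarray:
        """Scores aligned with the input instance order."""
        out = np.zeros((len(instances), self.cfg.n_classes))
        for batch in batch_instances(instances, batch_size):
            out[batch.indices] = self.predict(batch)
        return out

    def probe_widths(self) -> dict[str, int]:
        """Concatenation/pooling widths measured from an actual forward pass."""
        dummy = CandidateBatch(
            token_ids=np.zeros((1, 4), dtype=np.intp),
            context_features=np.zeros((1, 4, N_CONTEXT_FEATURES)),
            pair_features=np.zeros((1, 4, N_PAIR_FEATURES)),
            labels=np.zeros(1, dtype=np.intp), indices=np.arange(1))
        scores, aux = self.forward(dummy)
        return {"c3": aux["c3"].shape[-1], "l3": aux["l3"].shape[-1],
                "p1": aux["p1"].shape[-1], "d5": scores.shape[-1]}


def _named_params(shared, pretrain_net=None, recog_net=None):
    named = {}
    seen = set()
    sources = [("shared", shared.params)]
    if pretrain_net is not None:
        sources.append(("pretrain", pretrain_net.params))
    if recog_net is not None:
        sources.append(("recog", recog_net.params))
    for prefix, params in sources:
        for i, p in enumerate(params):
            if id(p) not in seen:
                seen.add(id(p))
                named[f"{prefix}.{i}"] = p
    return named


def save_checkpoint(path, shared, pretrain_net=None, recog_net=None,
                    meta: dict | None = None):
    """All unique parameter tensors to an .npz, metadata to a sibling .json."""
    path = Path(path)
    named = _named_params(shared, pretrain_net, recog_net)
    np.savez(path, **{k: v.data for k, v in named.items()})
    meta_path = path.with_suffix(".json")
    meta_path.write_text(json.dumps(meta or {}, indent=1), encoding="utf-8")


def load_checkpoint(path, shared, pretrain_net=None, recog_net=None) -> dict:
    """Restore parameters in place; returns the checkpoint metadata."""
    path = Path(path)
    npz = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    named = _named_params(shared, pretrain_net, recog_net)
    for key, p in named.items():
        if key in npz:
            if npz[key].shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch for {key}")
            p.data[...] = npz[key]
    meta_path = path.with_suffix(".json")
    return json.loads(meta_path.read_text(encoding="utf-8")) if meta_path.exists() else {}
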