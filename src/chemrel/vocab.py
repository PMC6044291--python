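"""Token vocabulary and initial embedding matrix.

Tokens seen fewer than ``min_count`` times (default 2) in the task training
corpus are out-of-vocabulary and map to UNK at lookup time.  Five indices are
reserved: padding, unknown, and the three entity-mask placeholders used when
building candidate instances.  Embedding rows are copied from a GloVe table
where available; rows for corpus tokens absent from the table, and all
reserved rows, start at zero.  Every row is trainable downstream — the
pre-training phase is what gives the mask and unseen-token rows useful
values.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path

import numpy as np

from .corpus import CorpusError, GloveTable

__all__ = ["Vocab", "build_vocab", "build_embedding_matrix",
           "save_embeddings", "load_embeddings",
           "PAD", "UNK", "MASK_CHEMICAL", "MASK_PROTEIN", "MASK_BOTH"]

PAD, UNK, MASK_CHEMICAL, MASK_PROTEIN, MASK_BOTH = 0, 1, 2, 3, 4

RESERVED = ["<PAD>", "<UNK>", "$CHEMICAL", "$PROTEIN", "$BOTH"]


class Vocab:
    """Dense token -> index mapping with reserved special indices."""

    PAD, UNK = PAD, UNK
    MASK_CHEMICAL, MASK_PROTEIN, MASK_BOTH = MASK_CHEMICAL, MASK_PROTEIN, MASK_BOTH

    def __init__(self, tokens: list[str], min_count: int = 2):
        self.min_count = min_count
        self._tokens = list(RESERVED) + [t for t in tokens if t not in RESERVED]
        self._index = {t: i for i, t in enumerate(self._tokens)}

    def __len__(self):
        return len(self._tokens)

    def __contains__(self, token):
        return token in self._index

    def __getitem__(self, token: str) -> int:
        """Total lookup: unseen tokens map to UNK."""
        return self._index.get(token, UNK)

    def encode(self, tokens) -> np.ndarray:
        return np.array([self[t] for t in tokens], dtype=np.intp)

    def token(self, idx: int) -> str:
        return self._tokens[idx]

    @property
    def tokens(self) -> list[str]:
        return list(self._tokens)

    @property
    def corpus_tokens(self) -> list[str]:
        return self._tokens[len(RESERVED):]

    def to_json(self, path):
        Path(path).write_text(json.dumps(
            {"min_count": self.min_count, "tokens": self.corpus_tokens}),
            encoding="utf-8")

    @classmethod
    def from_json(cls, path):
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(obj["tokens"], min_count=obj["min_count"])


def build_vocab(token_streams, min_count: int = 2) -> Vocab:
    """Count tokens over an iterable of token sequences and keep the frequent.

    Retained tokens are ordered by descending count (ties alphabetically) so
    that index assignment is deterministic.
    """
    counts = Counter()
    for stream in token_streams:
        counts.update(stream)
    kept = sorted((t for t, c in counts.items() if c >= min_count),
                  key=lambda t: (-counts[t], t))
    return Vocab(kept, min_count=min_count)


def build_embedding_matrix(vocab: Vocab, glove: GloveTable,
                           dim: int | None = None) -> np.ndarray:
    """(V, d) initial embedding matrix; GloVe rows copied, the rest zero."""
    if dim is None:
        dim = glove.dim
    if len(glove) > 0 and glove.dim != dim:
        raise CorpusError(
            f"GloVe dimension {glove.dim} != configured dimension {dim}")
    mat = np.zeros((len(vocab), dim))
    for i, tok in enumerate(vocab.tokens):
        if i >= len(RESERVED) and tok in glove:
            mat[i] = glove[tok]
    return mat


def save_embeddings(matrix: np.ndarray, vocab: Vocab, prefix) -> None:
    """Checkpoint the matrix (.npy) alongside its token-index map (.json)."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), matrix)
    vocab.to_json(prefix.with_suffix(".json"))


def load_embeddings(prefix) -> tuple[np.ndarray, Vocab]:
    prefix = Path(prefix)
    return (np.load(prefix.with_suffix(".npy")),
            Vocab.from_json(prefix.with_suffix(".json")))
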