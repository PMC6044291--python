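"""The negative-sample discrimination task used for phase-1 pre-training.

Unlabelled text (one paragraph per line) is consumed in sub-epochs of
``n`` lines.  Within a sub-epoch each token of each line is replaced, with
probability 0.5, by a token drawn uniformly from all token occurrences in
that sub-epoch's lines ("negative samples").  The network sees the original
sequence plus the substituted sequence shifted one step right and one step
left, and must flag, per position, whether the shifted token is original (1)
or substituted (0).  Losses at the pad positions introduced by shifting or
by batch padding are masked out.

A replacement is counted as a replacement even when the sampled token
happens to equal the original: the target records the substitution event,
not value equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .vocab import PAD, Vocab

logger = logging.getLogger(__name__)

__all__ = ["LineSource", "PretrainExample", "LengthBatch", "sample_subepoch",
           "substitute", "make_example", "batch_by_length", "group_by_length",
           "build_subepoch_batches"]


class LineSource:
    """Sequential reader over pre-training lines, cycling at end of data.

    Wraps either a path to a text file or an in-memory list of lines.  The
    cursor persists across sub-epochs so successive sub-epochs see successive
    slices of the file, wrapping (with a log message) when it is exhausted.
    """

    def __init__(self, source):
        if isinstance(source, (str, Path)):
            self._lines = Path(source).read_text(encoding="utf-8").splitlines()
        else:
            self._lines = list(source)
        self._lines = [l for l in self._lines if l.strip()]
        if not self._lines:
            raise ValueError("pre-training line source is empty")
        self._cursor = 0
        self.lines_read = 0

    def reset(self):
        """Rewind to the first line (training runs restart the cursor)."""
        self._cursor = 0
        self.lines_read = 0

    def __len__(self):
        return len(self._lines)

    def take(self, n: int) -> list[str]:
        out = []
        while len(out) < n:
            if self._cursor == len(self._lines):
                self._cursor = 0
                logger.info("line source exhausted after %d lines; cycling",
                            self.lines_read)
            out.append(self._lines[self._cursor])
            self._cursor += 1
            self.lines_read += 1
        return out


def sample_subepoch(line_source: LineSource, n: int = 12000,
                    tokenizer=None) -> list[list[str]]:
    """Read and tokenize the next ``n`` lines of the source."""
    from .tokenize import tokenize_with_spans
    tokenizer = tokenizer or tokenize_with_spans
    return [[t.surface for t in tokenizer(line)]
            for line in line_source.take(n)]


def substitute(token_ids: np.ndarray, pool: np.ndarray, p: float = 0.5,
               rng: np.random.Generator | None = None):
    """Replace each position independently with probability ``p``.

    ``pool`` is the flat array of all token ids in the sub-epoch, so sampling
    an index uniformly is occurrence-weighted sampling of tokens.  Returns
    ``(substituted, flags)`` with ``flags[i] = 0`` iff position i was
    replaced.
    """
    if len(pool) == 0:
        raise ValueError("substitution pool is empty")
    rng = rng or np.random.default_rng()
    token_ids = np.asarray(token_ids, dtype=np.intp)
    replaced = rng.random(len(token_ids)) < p
    out = token_ids.copy()
    out[replaced] = pool[rng.integers(0, len(pool), size=int(replaced.sum()))]
    flags = (~replaced).astype(np.float64)
    return out, flags


@dataclass
class PretrainExample:
    """One line's inputs/targets for the discrimination network.

    All sequences share one length L.  ``i2``/``i3`` are the substituted
    sequence shifted right/left with a PAD at the introduced position;
    ``mask_left``/``mask_right`` are zero exactly there (and, after
    batching, at batch-padding positions).
    """

    i1: np.ndarray        # original token ids
    i2: np.ndarray        # substituted, shifted right (PAD first)
    i3: np.ndarray        # substituted, shifted left (PAD last)
    y_left: np.ndarray    # 1 original / 0 substituted, aligned with i2
    y_right: np.ndarray   # aligned with i3
    mask_left: np.ndarray
    mask_right: np.ndarray

    def __len__(self):
        return len(self.i1)


def make_example(original: np.ndarray, substituted: np.ndarray,
                 flags: np.ndarray) -> PretrainExample:
    original = np.asarray(original, dtype=np.intp)
    substituted = np.asarray(substituted, dtype=np.intp)
    flags = np.asarray(flags, dtype=np.float64)
    if not (len(original) == len(substituted) == len(flags)):
        raise ValueError("sequence lengths differ")
    n = len(original)
    i2 = np.concatenate(([PAD], substituted[:-1])) if n else substituted
    i3 = np.concatenate((substituted[1:], [PAD])) if n else substituted
    y_left = np.concatenate(([0.0], flags[:-1])) if n else flags
    y_right = np.concatenate((flags[1:], [0.0])) if n else flags
    mask_left = np.ones(n)
    mask_right = np.ones(n)
    if n:
        mask_left[0] = 0.0
        mask_right[-1] = 0.0
    return PretrainExample(original, i2, i3, y_left, y_right,
                           mask_left, mask_right)


@dataclass
class LengthBatch:
    """Up to ``batch_size`` examples padded to a common length."""

    i1: np.ndarray        # (B, T) int
    i2: np.ndarray
    i3: np.ndarray
    y_left: np.ndarray    # (B, T) float
    y_right: np.ndarray
    mask_left: np.ndarray
    mask_right: np.ndarray

    @property
    def n(self):
        return self.i1.shape[0]


def group_by_length(items, batch_size: int = 32):
    """Stable sort by length, then chunk into groups of <= batch_size."""
    order = sorted(range(len(items)), key=lambda i: len(items[i]))
    return [[items[i] for i in order[k:k + batch_size]]
            for k in range(0, len(order), batch_size)]


def _pad_to(arr, t, fill):
    out = np.full(t, fill, dtype=arr.dtype)
    out[:len(arr)] = arr
    return out


def batch_by_length(examples: list[PretrainExample],
                    batch_size: int = 32) -> list[LengthBatch]:
    """Group the smallest ``batch_size`` examples together, pad per group."""
    batches = []
    for group in group_by_length(examples, batch_size):
        t = max(len(ex) for ex in group)
        batches.append(LengthBatch(
            i1=np.stack([_pad_to(ex.i1, t, PAD) for ex in group]),
            i2=np.stack([_pad_to(ex.i2, t, PAD) for ex in group]),
            i3=np.stack([_pad_to(ex.i3, t, PAD) for ex in group]),
            y_left=np.stack([_pad_to(ex.y_left, t, 0.0) for ex in group]),
            y_right=np.stack([_pad_to(ex.y_right, t, 0.0) for ex in group]),
            mask_left=np.stack([_pad_to(ex.mask_left, t, 0.0) for ex in group]),
            mask_right=np.stack([_pad_to(ex.mask_right, t, 0.0) for ex in group]),
        ))
    return batches


def build_subepoch_batches(lines: list[list[str]], vocab: Vocab,
                           p: float = 0.5, batch_size: int = 32,
                           rng: np.random.Generator | None = None):
    """Full sub-epoch pipeline: encode, substitute, shift, batch."""
    rng = rng or np.random.default_rng()
    encoded = [vocab.encode(toks) for toks in lines if toks]
    pool = np.concatenate(encoded) if encoded else np.array([], dtype=np.intp)
    examples = []
    for ids in encoded:
        sub, flags = substitute(ids, pool, p=p, rng=rng)
        examples.append(make_example(ids, sub, flags))
    return batch_by_length(examples, batch_size)
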