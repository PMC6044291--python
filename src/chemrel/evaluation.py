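"""CHEMPROT-style scoring.

Relations are scored as unique (doc_id, group, chem_id, gene_id) tuples:
micro-averaged precision = |preds ∩ gold| / |preds|, recall =
|preds ∩ gold| / |gold|, F = harmonic mean, all as percentages reported to
two decimals (half-up, matching how such results are conventionally
printed).  Per-class scores restrict both sets to one CPR group.  The
confusion matrix is computed at the candidate level (one row per candidate
pair, not deduplicated), actual label in rows, predicted in columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .corpus import CprGroup

__all__ = ["PRF", "PerClassResult", "f_score", "micro_prf", "per_class_prf",
           "confusion", "candidate_micro_prf", "LABEL_NAMES"]

LABEL_NAMES = ["NONE", "CPR:3", "CPR:4", "CPR:5", "CPR:6", "CPR:9"]


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PRF:
    """Precision, recall and F as percentages (two decimals)."""

    precision: float
    recall: float
    f: float

    @classmethod
    def from_counts(cls, tp: int, n_pred: int, n_gold: int) -> "PRF":
        p = 100.0 * tp / n_pred if n_pred else 0.0
        r = 100.0 * tp / n_gold if n_gold else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return cls(_round2(p), _round2(r), _round2(f))


@dataclass(frozen=True)
class PerClassResult:
    prf: PRF
    n_gold: int
    n_pred: int

    @property
    def no_instances(self) -> bool:
        return self.n_gold == 0 and self.n_pred == 0


def f_score(p: float, r: float) -> float:
    """Harmonic mean of precision/recall percentages, to two decimals."""
    if not (0 <= p <= 100 and 0 <= r <= 100):
        raise ValueError("precision/recall must be percentages in [0, 100]")
    if p + r == 0:
        return 0.0
    return _round2(2 * p * r / (p + r))


def micro_prf(preds, gold) -> PRF:
    """Micro-averaged P/R/F over unique relation tuples."""
    pred_set, gold_set = set(preds), set(gold)
    tp = len(pred_set & gold_set)
    return PRF.from_counts(tp, len(pred_set), len(gold_set))


def per_class_prf(preds, gold) -> dict[CprGroup, PerClassResult]:
    """micro_prf restricted to each CPR group's tuples."""
    pred_set, gold_set = set(preds), set(gold)
    out = {}
    for group in CprGroup:
        p_g = {t for t in pred_set if t[1] is group}
        g_g = {t for t in gold_set if t[1] is group}
        out[group] = PerClassResult(
            PRF.from_counts(len(p_g & g_g), len(p_g), len(g_g)),
            n_gold=len(g_g), n_pred=len(p_g))
    return out


def confusion(actual, predicted, n_classes: int = 6) -> np.ndarray:
    """Candidate-level confusion matrix; rows actual, columns predicted."""
    actual = np.asarray(actual, dtype=np.intp)
    predicted = np.asarray(predicted, dtype=np.intp)
    if actual.shape != predicted.shape:
        raise ValueError("label arrays differ in length")
    if ((actual < 0) | (actual >= n_classes)
            | (predicted < 0) | (predicted >= n_classes)).any():
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (actual, predicted), 1)
    return mat


def candidate_micro_prf(actual, predicted) -> PRF:
    """Micro P/R/F at the candidate level (label 0 = no relation).

    A candidate counts as a true positive when a nonzero label is predicted
    and matches; used for threshold fitting where candidates, not unique
    relation tuples, are in hand.
    """
    actual = np.asarray(actual, dtype=np.intp)
    predicted = np.asarray(predicted, dtype=np.intp)
    tp = int(((predicted != 0) & (predicted == actual)).sum())
    return PRF.from_counts(tp, int((predicted != 0).sum()),
                           int((actual != 0).sum()))
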