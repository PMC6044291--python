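"""Turning 6-way score vectors into relation decisions.

The plain decision is the argmax of all six outputs.  The rebalancing
decision first takes the best *positive* class x = argmax of the five
relation scores, with o_x its score and o_0 the NONE score, then computes
one of three statistics:

    a = o_x        b = o_x - o_0        c = o_x / o_0

and accepts x iff the statistic is strictly above a threshold (otherwise
NONE).  Formula and threshold are fitted jointly by maximising micro-F on
development data; since F only changes at observed statistic values, the
search grid of midpoints between consecutive distinct dev values (plus one
point below the minimum and one above the maximum) is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .evaluation import candidate_micro_prf

__all__ = ["Formula", "ThresholdRule", "argmax_decision", "threshold_value",
           "thresholded_decision", "fit_threshold"]


class Formula(Enum):
    A = "a"   # raw best-positive score
    B = "b"   # margin over NONE
    C = "c"   # ratio to NONE


@dataclass(frozen=True)
class ThresholdRule:
    formula: Formula
    threshold: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"formula": self.formula.value, "threshold": self.threshold}),
            encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "ThresholdRule":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(Formula(obj["formula"]), float(obj["threshold"]))


def argmax_decision(scores) -> int:
    """Index of the maximum score; ties go to the lowest index."""
    return int(np.argmax(np.asarray(scores)))


def _positive_argmax(scores: np.ndarray) -> np.ndarray:
    return np.argmax(scores[..., 1:], axis=-1) + 1


def threshold_value(scores, formula: Formula) -> float:
    """The rebalancing statistic for one score vector."""
    s = np.asarray(scores, dtype=np.float64)
    x = int(_positive_argmax(s))
    o_x, o_0 = s[x], s[0]
    if formula is Formula.A:
        return float(o_x)
    if formula is Formula.B:
        return float(o_x - o_0)
    return float(o_x / o_0) if o_0 > 0 else float("inf")


def thresholded_decision(scores, rule: ThresholdRule) -> int:
    """Best positive class if its statistic exceeds the threshold, else NONE."""
    s = np.asarray(scores, dtype=np.float64)
    x = int(_positive_argmax(s))
    return x if threshold_value(s, rule.formula) > rule.threshold else 0


def _stat_array(scores: np.ndarray, formula: Formula) -> np.ndarray:
    xs = _positive_argmax(scores)
    o_x = scores[np.arange(len(scores)), xs]
    o_0 = scores[:, 0]
    if formula is Formula.A:
        return o_x
    if formula is Formula.B:
        return o_x - o_0
    with np.errstate(divide="ignore"):
        return np.where(o_0 > 0, o_x / np.where(o_0 > 0, o_0, 1.0), np.inf)


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    finite = np.unique(values[np.isfinite(values)])
    if len(finite) == 0:
        return np.array([0.0])
    mids = (finite[:-1] + finite[1:]) / 2.0
    return np.concatenate(([finite[0] - 1.0], mids, [finite[-1] + 1.0]))


def fit_threshold(dev_scores, dev_labels, evaluator=None) -> ThresholdRule:
    """Jointly fit formula and threshold maximising dev micro-F.

    ``dev_scores``: (n, 6) array of score vectors; ``dev_labels``: gold
    labels 0..5.  ``evaluator(predicted_labels) -> F`` may be supplied to
    score against something other than candidate-level micro-F (e.g. unique
    relation tuples).  Ties prefer formula order a, b, c, then the lower
    threshold.
    """
    scores = np.asarray(dev_scores, dtype=np.float64)
    labels = np.asarray(dev_labels, dtype=np.intp)
    if len(scores) == 0:
        raise ValueError("empty development set")
    if evaluator is None:
        evaluator = lambda pred: candidate_micro_prf(labels, pred).f
    xs = _positive_argmax(scores)
    best = None
    for formula in Formula:
        stats = _stat_array(scores, formula)
        for thr in _candidate_thresholds(stats):
            pred = np.where(stats > thr, xs, 0)
            f = evaluator(pred)
            if best is None or f > best[0] + 1e-12:
                best = (f, formula, float(thr))
    return ThresholdRule(best[1], best[2])
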