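"""Two-phase training schedule, per-epoch evaluation and epoch selection.

Each of the first ``phase1_epochs`` epochs runs phase 1 (a configurable
number of 12 000-line sub-epochs of negative-sample pre-training on the
unlabelled text) followed by phase 2 (one pass over the labelled candidate
instances); later epochs run phase 2 only.  After every epoch the
development set is scored (argmax decisions, micro P/R/F over unique
relation tuples) and, if a test set is present, an answer file is produced.
The epoch with the best development F is selected afterwards; threshold
rebalancing is a separate post-hoc step applied to the stored per-epoch
development scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .candidates import batch_instances, build_document_instances
from .corpus import GROUP_FOR_LABEL, RelationGold, write_predictions
from .decision import argmax_decision
from .evaluation import PRF, micro_prf
from .models import (ModelConfig, PretrainingNetwork, RecognitionNetwork,
                     SharedLayers, save_checkpoint)
from .pretrain import LineSource, build_subepoch_batches, sample_subepoch

logger = logging.getLogger(__name__)

__all__ = ["Schedule", "CorpusBundle", "EpochRecord", "TrainingResult",
           "run_training", "select_best_epoch", "simulate_schedule",
           "predictions_from_scores", "relation_tuples"]


@dataclass(frozen=True)
class Schedule:
    """Training schedule; defaults are the full-scale ones."""

    n_epochs: int = 50
    phase1_epochs: int = 5
    subepochs_per_epoch: int = 25     # 0 disables phase 1 entirely
    lines_per_subepoch: int = 12000
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.subepochs_per_epoch <= 25:
            raise ValueError("subepochs_per_epoch must be in 0..25")
        if self.n_epochs < 1 or self.phase1_epochs < 0:
            raise ValueError("invalid epoch counts")

    @property
    def phase1_line_budget(self) -> int:
        return (min(self.phase1_epochs, self.n_epochs)
                * self.subepochs_per_epoch * self.lines_per_subepoch)


@dataclass
class CorpusBundle:
    """Everything one training run consumes."""

    vocab: object             # Vocab shared by both phases
    train_instances: list
    dev_instances: list
    dev_gold: list            # RelationGold for the dev split
    pretrain_lines: LineSource | None = None
    test_instances: list = field(default_factory=list)


@dataclass
class EpochRecord:
    epoch: int                # 1-based
    dev_prf: PRF
    phase1_lines: int         # cumulative
    train_loss: float
    dev_scores: np.ndarray    # (n_dev, 6)
    test_scores: np.ndarray | None = None


@dataclass
class TrainingResult:
    epochs: list[EpochRecord]
    shared: SharedLayers
    recognition: RecognitionNetwork
    pretraining: PretrainingNetwork | None

    @property
    def dev_f_log(self) -> list[float]:
        return [r.dev_prf.f for r in self.epochs]

    @property
    def best_epoch(self) -> int:
        return select_best_epoch(self.dev_f_log)


def select_best_epoch(dev_f_log) -> int:
    """1-based index of the best development F; ties -> earliest epoch."""
    if len(dev_f_log) == 0:
        raise ValueError("empty metric log")
    arr = np.asarray(dev_f_log, dtype=np.float64)
    return int(np.argmax(arr)) + 1


def relation_tuples(instances, labels):
    """Unique (doc, group, chem, gene) tuples for nonzero predicted labels."""
    out = set()
    for inst, lab in zip(instances, labels):
        if lab != 0:
            out.add((inst.doc_id, GROUP_FOR_LABEL[int(lab)],
                     inst.chem_id, inst.gene_id))
    return out


def predictions_from_scores(instances, scores, decide=None):
    """Apply a decision function to scores and collect RelationGold records."""
    decide = decide or argmax_decision
    preds = []
    for inst, s in zip(instances, scores):
        lab = decide(s)
        if lab != 0:
            preds.append(RelationGold(inst.doc_id, GROUP_FOR_LABEL[lab],
                                      inst.chem_id, inst.gene_id))
    return preds


def build_corpus_bundle(train, dev, vocab, pretrain_lines=None, test=None,
                        max_distance: int = 60, context: int = 5) -> CorpusBundle:
    """Turn (abstracts, entities, relations) triples into instance sets."""

    def instances(split, with_gold=True):
        abstracts, entities, relations = split
        out = []
        for ab in abstracts:
            out.extend(build_document_instances(
                ab, entities, relations if with_gold else [], vocab,
                max_distance=max_distance, context=context))
        return out

    return CorpusBundle(
        vocab=vocab,
        train_instances=instances(train),
        dev_instances=instances(dev),
        dev_gold=list(dev[2]),
        pretrain_lines=(LineSource(pretrain_lines)
                        if pretrain_lines is not None else None),
        test_instances=instances(test, with_gold=False) if test else [],
    )


def _evaluate_dev(recognition, bundle, batch_size):
    scores = recognition.predict_instances(bundle.dev_instances, batch_size)
    labels = [argmax_decision(s) for s in scores]
    preds = relation_tuples(bundle.dev_instances, labels)
    gold = {r.tuple() for r in bundle.dev_gold}
    return micro_prf(preds, gold), scores


def run_training(bundle: CorpusBundle, schedule: Schedule, cfg: ModelConfig,
                 embedding_init=None, out_dir=None,
                 keep_scores: bool = True) -> TrainingResult:
    """Run the full two-phase schedule and return the per-epoch log.

    ``out_dir``, when given, receives per-epoch checkpoints and, if test
    instances are present, per-epoch answer files.  All randomness flows
    from ``schedule.seed``.
    """
    rng = np.random.default_rng(schedule.seed)
    shared = SharedLayers(cfg, len(bundle.vocab), rng, embedding_init)
    recognition = RecognitionNetwork(cfg, shared, rng)
    use_phase1 = schedule.subepochs_per_epoch > 0 and schedule.phase1_epochs > 0
    pretraining = PretrainingNetwork(cfg, shared, rng) if use_phase1 else None
    if use_phase1 and bundle.pretrain_lines is None:
        raise ValueError("phase 1 enabled but no pre-training text given")
    if use_phase1:
        bundle.pretrain_lines.reset()

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    records = []
    phase1_lines = 0
    train_batches = batch_instances(bundle.train_instances, schedule.batch_size)
    for epoch in range(1, schedule.n_epochs + 1):
        if use_phase1 and epoch <= schedule.phase1_epochs:
            for _ in range(schedule.subepochs_per_epoch):
                lines = sample_subepoch(bundle.pretrain_lines,
                                        schedule.lines_per_subepoch)
                phase1_lines += len(lines)
                batches = build_subepoch_batches(
                    lines, vocab=bundle.vocab,
                    batch_size=schedule.batch_size, rng=rng)
                for b_idx in rng.permutation(len(batches)):
                    pretraining.train_step(batches[b_idx], rng)
        losses = []
        for b_idx in rng.permutation(len(train_batches)):
            losses.append(recognition.train_step(train_batches[b_idx], rng))
        dev_prf, dev_scores = _evaluate_dev(recognition, bundle,
                                            schedule.batch_size)
        test_scores = None
        if bundle.test_instances:
            test_scores = recognition.predict_instances(
                bundle.test_instances, schedule.batch_size)
            if out_dir is not None:
                preds = predictions_from_scores(bundle.test_instances,
                                                test_scores)
                write_predictions(preds, out_dir / f"answers_epoch{epoch}.tsv")
        if out_dir is not None:
            save_checkpoint(out_dir / f"epoch{epoch}.npz", shared,
                            pretraining, recognition,
                            meta={"epoch": epoch,
                                  "dev_precision": dev_prf.precision,
                                  "dev_recall": dev_prf.recall,
                                  "dev_f": dev_prf.f})
        logger.info("epoch %d: dev P=%.2f R=%.2f F=%.2f (loss %.4f)",
                    epoch, dev_prf.precision, dev_prf.recall, dev_prf.f,
                    float(np.mean(losses)) if losses else float("nan"))
        records.append(EpochRecord(
            epoch=epoch, dev_prf=dev_prf, phase1_lines=phase1_lines,
            train_loss=float(np.mean(losses)) if losses else float("nan"),
            dev_scores=dev_scores if keep_scores else np.empty((0, 0)),
            test_scores=test_scores))
    return TrainingResult(records, shared, recognition, pretraining)


def simulate_schedule(schedule: Schedule, line_source: LineSource | None = None):
    """Dry-run the schedule loop, counting phase-1 line consumption only.

    Mirrors run_training's control flow without building or training any
    network; with a real line source the counter advances by actually
    drawing lines from it.
    """
    phase1_lines = 0
    phase1_runs = 0
    for epoch in range(1, schedule.n_epochs + 1):
        if schedule.subepochs_per_epoch > 0 and epoch <= schedule.phase1_epochs:
            phase1_runs += 1
            for _ in range(schedule.subepochs_per_epoch):
                if line_source is not None:
                    phase1_lines += len(
                        line_source.take(schedule.lines_per_subepoch))
                else:
                    phase1_lines += schedule.lines_per_subepoch
    return {"phase1_lines": phase1_lines, "phase1_runs": phase1_runs,
            "n_epochs": schedule.n_epochs}
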