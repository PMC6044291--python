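"""Candidate chemical-protein pairs and their network inputs.

Every CHEMICAL x GENE mention pair whose token span is short enough becomes a
candidate: the window from 5 tokens before the earlier entity to 5 tokens
after the later one is cut out, the candidate chemical's tokens are replaced
by the ``$CHEMICAL`` placeholder, the gene's by ``$PROTEIN`` and tokens in
both by ``$BOTH`` (one placeholder per original token), and two aligned
feature sequences are attached:

* ``entity_context_features`` (10 bits/token): the five span-overlap flags
  against any chemical entity in the document and the same five against any
  gene entity — the classifier sees where *all* entities sit, not just the
  candidate pair;
* ``pair_features`` (2 bits/token): whether the token belongs to the
  candidate chemical / candidate gene.

Labels are 6-way: 0 for NONE, then CPR:3, CPR:4, CPR:5, CPR:6, CPR:9.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .corpus import CprGroup, EntityKind, EntityMention, RelationGold
from .tokenize import TokenSpan, overlap_flags
from .vocab import MASK_BOTH, MASK_CHEMICAL, MASK_PROTEIN, Vocab

logger = logging.getLogger(__name__)

__all__ = ["CandidateInstance", "entity_token_indices", "enumerate_pairs",
           "build_instance", "label_candidate", "build_document_instances",
           "instances_to_jsonl", "CandidateBatch", "batch_instances",
           "document_context_features",
           "N_CONTEXT_FEATURES", "N_PAIR_FEATURES"]

N_CONTEXT_FEATURES = 10
N_PAIR_FEATURES = 2


@dataclass
class CandidateInstance:
    doc_id: str
    chem_id: str
    gene_id: str
    token_ids: np.ndarray                 # (T,) vocab indices
    entity_context_features: np.ndarray   # (T, 10) uint8
    pair_features: np.ndarray             # (T, 2) uint8
    label: int
    masked_surfaces: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.token_ids)


def entity_token_indices(tokens: list[TokenSpan], entity: EntityMention) -> list[int]:
    """Indices of tokens belonging to the entity (any overlap flag set)."""
    return [i for i, tok in enumerate(tokens) if overlap_flags(tok, entity).any]


def _ordered(first_tok_a, ent_a, first_tok_b, ent_b):
    ka = (first_tok_a, ent_a.char_start)
    kb = (first_tok_b, ent_b.char_start)
    return (ka, kb) if ka <= kb else (kb, ka)


def enumerate_pairs(tokens: list[TokenSpan], entities: list[EntityMention],
                    max_distance: int = 60):
    """All CHEMICAL x GENE pairs within the token-distance window.

    The distance is the index of the later entity's last token minus the
    index of the earlier entity's first token ("earlier" by first-token
    index, ties by char_start); pairs with distance <= ``max_distance``
    are kept.  Entities overlapping no token are skipped with a warning.
    Returns ``(chem, gene)`` pairs in deterministic corpus order.
    """
    spans = {}
    for ent in entities:
        idx = entity_token_indices(tokens, ent)
        if not idx:
            logger.warning("entity %s/%s overlaps no token; skipped",
                           ent.doc_id, ent.entity_id)
            continue
        spans[ent.entity_id] = (idx[0], idx[-1])
    chems = [e for e in entities if e.kind is EntityKind.CHEMICAL
             and e.entity_id in spans]
    genes = [e for e in entities if e.kind is EntityKind.GENE
             and e.entity_id in spans]
    pairs = []
    for chem in chems:
        cf, cl = spans[chem.entity_id]
        for gene in genes:
            gf, gl = spans[gene.entity_id]
            if (cf, chem.char_start) <= (gf, gene.char_start):
                distance = gl - cf
            else:
                distance = cl - gf
            if distance <= max_distance:
                pairs.append((chem, gene))
    return pairs


def label_candidate(chem: EntityMention, gene: EntityMention,
                    gold: list[RelationGold]) -> int:
    """6-way label for the pair; several gold groups resolve to the lowest."""
    groups = sorted(
        {r.group.label_index for r in gold
         if r.doc_id == chem.doc_id and r.chem_id == chem.entity_id
         and r.gene_id == gene.entity_id})
    if not groups:
        return 0
    if len(groups) > 1:
        logger.warning(
            "pair %s/%s-%s has %d gold groups; keeping the lowest",
            chem.doc_id, chem.entity_id, gene.entity_id, len(groups))
    return groups[0]


def document_context_features(tokens: list[TokenSpan],
                              entities: list[EntityMention]) -> np.ndarray:
    """(T, 10) all-entity overlap features, shared by every candidate."""
    feats = np.zeros((len(tokens), N_CONTEXT_FEATURES), dtype=np.uint8)
    for ent in entities:
        off = 0 if ent.kind is EntityKind.CHEMICAL else 5
        for i, tok in enumerate(tokens):
            flags = overlap_flags(tok, ent)
            if flags.any:
                feats[i, off:off + 5] |= np.array(flags, dtype=np.uint8)
    return feats


def build_instance(tokens: list[TokenSpan], all_entities: list[EntityMention],
                   chem: EntityMention, gene: EntityMention, vocab: Vocab,
                   gold: list[RelationGold] | None = None,
                   context: int = 5,
                   doc_context: np.ndarray | None = None) -> CandidateInstance:
    """Masked, feature-annotated window for one candidate pair."""
    if doc_context is None:
        doc_context = document_context_features(tokens, all_entities)
    chem_set = set(entity_token_indices(tokens, chem))
    gene_set = set(entity_token_indices(tokens, gene))
    first = min(min(chem_set), min(gene_set))
    last = max(max(chem_set), max(gene_set))
    lo = max(0, first - context)
    hi = min(len(tokens) - 1, last + context)

    window = range(lo, hi + 1)
    ids = np.empty(len(window), dtype=np.intp)
    surfaces = []
    pair_feats = np.zeros((len(window), N_PAIR_FEATURES), dtype=np.uint8)
    ctx_feats = np.array(doc_context[lo:hi + 1], dtype=np.uint8)

    for j, i in enumerate(window):
        in_chem, in_gene = i in chem_set, i in gene_set
        if in_chem and in_gene:
            ids[j], surf = MASK_BOTH, "$BOTH"
        elif in_chem:
            ids[j], surf = MASK_CHEMICAL, "$CHEMICAL"
        elif in_gene:
            ids[j], surf = MASK_PROTEIN, "$PROTEIN"
        else:
            ids[j], surf = vocab[tokens[i].surface], tokens[i].surface
        surfaces.append(surf)
        pair_feats[j, 0] = in_chem
        pair_feats[j, 1] = in_gene

    label = label_candidate(chem, gene, gold) if gold is not None else 0
    return CandidateInstance(chem.doc_id, chem.entity_id, gene.entity_id,
                             ids, ctx_feats, pair_feats, label,
                             masked_surfaces=surfaces)


def build_document_instances(abstract, entities, gold, vocab,
                             tokenizer=None, max_distance: int = 60,
                             context: int = 5) -> list[CandidateInstance]:
    """All candidate instances for one abstract."""
    from .tokenize import tokenize_with_spans
    tokenizer = tokenizer or tokenize_with_spans
    tokens = tokenizer(abstract.text)
    doc_entities = [e for e in entities if e.doc_id == abstract.doc_id]
    doc_gold = [r for r in gold if r.doc_id == abstract.doc_id] if gold else []
    doc_context = document_context_features(tokens, doc_entities)
    out = []
    for chem, gene in enumerate_pairs(tokens, doc_entities, max_distance):
        out.append(build_instance(tokens, doc_entities, chem, gene, vocab,
                                  gold=doc_gold, context=context,
                                  doc_context=doc_context))
    return out


@dataclass
class CandidateBatch:
    """Length-grouped, padded batch of candidate instances.

    ``indices`` maps each row back to its position in the list the batch was
    built from, so predictions can be re-aligned with the instances.
    """

    token_ids: np.ndarray          # (B, T) intp, PAD-padded
    context_features: np.ndarray   # (B, T, 10) float
    pair_features: np.ndarray      # (B, T, 2) float
    labels: np.ndarray             # (B,) intp
    indices: np.ndarray            # (B,) intp

    @property
    def n(self):
        return self.token_ids.shape[0]


def batch_instances(instances, batch_size: int = 32) -> list[CandidateBatch]:
    """Group candidates by window length (smallest together), pad per group."""
    from .vocab import PAD
    order = sorted(range(len(instances)), key=lambda i: len(instances[i]))
    batches = []
    for k in range(0, len(order), batch_size):
        rows = order[k:k + batch_size]
        t = max(len(instances[i]) for i in rows)
        ids = np.full((len(rows), t), PAD, dtype=np.intp)
        ctx = np.zeros((len(rows), t, N_CONTEXT_FEATURES))
        pair = np.zeros((len(rows), t, N_PAIR_FEATURES))
        labels = np.empty(len(rows), dtype=np.intp)
        for r, i in enumerate(rows):
            inst = instances[i]
            ids[r, :len(inst)] = inst.token_ids
            ctx[r, :len(inst)] = inst.entity_context_features
            pair[r, :len(inst)] = inst.pair_features
            labels[r] = inst.label
        batches.append(CandidateBatch(ids, ctx, pair, labels,
                                      np.array(rows, dtype=np.intp)))
    return batches


def instances_to_jsonl(instances, path) -> None:
    """Debug dump: one JSON object per candidate with masked surfaces."""
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(json.dumps({
                "doc_id": inst.doc_id, "chem_id": inst.chem_id,
                "gene_id": inst.gene_id, "label": inst.label,
                "tokens": inst.masked_surfaces,
            }) + "\n")
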