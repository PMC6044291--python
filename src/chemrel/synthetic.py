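"""Desk-scale synthetic corpora for exercising the whole pipeline.

The generator emulates the three kinds of input the system consumes:

* annotated abstracts: template sentences of the form
  ``<chemical> <trigger> <protein>`` (a relation whose CPR group is a
  deterministic function of the trigger word), ``<chemical> and <protein>
  were measured`` (a co-occurring non-relation pair) and entity-free
  distractors, with exact character offsets and gold relations;
* unlabelled pre-training text: lines sampled from a first-order Markov
  grammar with strongly non-uniform transitions, so that randomly
  substituted tokens are statistically detectable from context;
* toy GloVe files over any token inventory.

Because the trigger lexicons are pairwise disjoint, an oracle reading only
the trigger scores F = 100 on a generated corpus: the ceiling is known, so
end-to-end recovery tests separate pipeline bugs from modelling noise.  The
grammar and the corpus share their token inventory, making phase-1 transfer
meaningful.  No linguistic realism is attempted: no negation, coordination
or cross-sentence relations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Abstract, CprGroup, EntityKind, EntityMention, RelationGold

__all__ = ["SynthConfig", "generate_corpus", "write_corpus_files",
           "generate_pretrain_text", "generate_toy_glove", "token_inventory"]

_DEFAULT_TRIGGERS = {
    CprGroup.CPR3: ("activates", "upregulates", "induces", "stimulates"),
    CprGroup.CPR4: ("inhibits", "downregulates", "suppresses", "blocks"),
    CprGroup.CPR5: ("agonizes", "potentiates"),
    CprGroup.CPR6: ("antagonizes", "counteracts"),
    CprGroup.CPR9: ("metabolizes", "converts", "processes"),
}

_FILLERS = (
    "the a of in and to was were is are by with for on at this that these "
    "results levels activity expression cells tissue patients study studies "
    "treatment effect effects signalling pathway receptor response dose "
    "significant observed measured analysed increased decreased compared "
    "control group groups data method methods we found show shown here "
    "report novel role during after before between both also may suggest "
    "suggests evidence binding assay values baseline samples human rat "
    "mouse liver plasma serum clinical trial model models mechanism "
    "mechanisms protein kinase enzyme gene not however further previous "
    "present total mean three two five using under over high low higher "
    "lower strongly markedly"
).split()

_CHEM_SYLS_A = ("dor", "flu", "mex", "tal", "ver", "nor", "cel", "rap",
                "lod", "bex", "san", "pir", "zol", "gab", "tem", "ric")
_CHEM_SYLS_B = ("a", "i", "o", "e", "u")
_CHEM_SUFFIX = ("mab", "nib", "olol", "pril", "statin", "azole", "idine",
                "amine", "oxin", "icin")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic corpus."""

    n_abstracts: int = 300
    n_chemicals: int = 40
    n_proteins: int = 40
    triggers: dict = field(default_factory=lambda: dict(_DEFAULT_TRIGGERS))
    non_relation_fraction: float = 0.3    # pair sentences without a relation
    distractor_rate: float = 0.15         # entity-free sentences
    min_sentences: int = 7
    max_sentences: int = 10
    lexicon_seed: int = 7                 # fixes the token inventory itself

    def __post_init__(self):
        flat = [t for ts in self.triggers.values() for t in ts]
        if len(set(flat)) != len(flat):
            raise ValueError("trigger lexicons must be pairwise disjoint")


def _lexicons(cfg: SynthConfig):
    """Deterministic chemical/protein name lists from the lexicon seed."""
    rng = np.random.default_rng(cfg.lexicon_seed)
    chems = set()
    while len(chems) < cfg.n_chemicals:
        chems.add(rng.choice(_CHEM_SYLS_A) + rng.choice(_CHEM_SYLS_B)
                  + rng.choice(_CHEM_SUFFIX))
    prots = set()
    letters = np.array(list("ABCDEFGHKLMNPRSTW"))
    while len(prots) < cfg.n_proteins:
        prots.add("".join(rng.choice(letters, size=3))
                  + str(rng.integers(1, 10)))
    return sorted(chems), sorted(prots)


def token_inventory(cfg: SynthConfig) -> list[str]:
    """All tokens the corpus and the pre-training grammar draw from."""
    chems, prots = _lexicons(cfg)
    trigs = [t for ts in cfg.triggers.values() for t in ts]
    return chems + prots + trigs + _FILLERS


def _pick(rng, options):
    return options[rng.integers(0, len(options))]


def _relation_sentence(rng, chem, prot, trigger):
    pre = _pick(rng, [[], ["we", "found", "that"], ["notably", ","]])
    adv = _pick(rng, [[], ["strongly"], ["markedly"]])
    post = _pick(rng, [[], ["in", "cells"], ["in", "patients"]])
    toks = [*pre, (chem, EntityKind.CHEMICAL), *adv, trigger,
            (prot, EntityKind.GENE), *post, "."]
    return list(toks)


def _nonrelation_sentence(rng, chem, prot):
    if rng.integers(0, 2) == 0:
        return [(chem, EntityKind.CHEMICAL), "and", (prot, EntityKind.GENE),
                "were", "measured", "."]
    return ["levels", "of", (chem, EntityKind.CHEMICAL), "and",
            (prot, EntityKind.GENE), "varied", "."]


def _filler_sentence(rng, n_lo=4, n_hi=8):
    n = rng.integers(n_lo, n_hi + 1)
    return [*rng.choice(_FILLERS, size=n).tolist(), "."]


def generate_corpus(cfg: SynthConfig, seed: int):
    """Generate ``(abstracts, entities, relations)`` records.

    Deterministic given ``(cfg, seed)``.  Every relation's mention pair sits
    inside one sentence, well within the 60-token candidate window.
    """
    rng = np.random.default_rng(seed)
    chems, prots = _lexicons(cfg)
    group_list = sorted(cfg.triggers, key=lambda g: g.value)
    abstracts, entities, relations = [], [], []

    for k in range(cfg.n_abstracts):
        doc_id = f"S{k + 1:04d}"
        title_toks = _filler_sentence(rng, 3, 6)[:-1]
        sentences = []       # list of (tokens, group-or-None)
        n_sent = rng.integers(cfg.min_sentences, cfg.max_sentences + 1)
        for _ in range(n_sent):
            u = rng.random()
            if u < cfg.distractor_rate:
                sentences.append((_filler_sentence(rng), None))
                continue
            chem = chems[rng.integers(0, len(chems))]
            prot = prots[rng.integers(0, len(prots))]
            if rng.random() < cfg.non_relation_fraction:
                sentences.append((_nonrelation_sentence(rng, chem, prot), None))
            else:
                group = group_list[rng.integers(0, len(group_list))]
                trig = cfg.triggers[group][rng.integers(0, len(cfg.triggers[group]))]
                sentences.append((_relation_sentence(rng, chem, prot, trig),
                                  group))

        title = " ".join(title_toks)
        cursor = len(title) + 1            # past the tab separator
        body_parts = []
        ent_count = 0
        for toks, group in sentences:
            sent_entities = {}
            for j, tok in enumerate(toks):
                if j > 0:
                    cursor += 1            # joining space
                if isinstance(tok, tuple):
                    surface, kind = tok
                    ent_count += 1
                    ent = EntityMention(doc_id, f"T{ent_count}", kind,
                                        cursor, cursor + len(surface), surface)
                    entities.append(ent)
                    sent_entities[kind] = ent
                    body_parts.append(surface)
                    cursor += len(surface)
                else:
                    body_parts.append(tok)
                    cursor += len(tok)
            body_parts.append(None)        # sentence boundary marker
            cursor += 1                    # space between sentences
            if group is not None:
                relations.append(RelationGold(
                    doc_id, group,
                    sent_entities[EntityKind.CHEMICAL].entity_id,
                    sent_entities[EntityKind.GENE].entity_id))
        cursor -= 1                        # no trailing space
        body = " ".join(" ".join(p for p in part if p is not None)
                        for part in _split_on_none(body_parts))
        abstracts.append(Abstract(doc_id, title, body))
    return abstracts, entities, relations


def _split_on_none(parts):
    chunk = []
    for p in parts:
        if p is None:
            if chunk:
                yield chunk
            chunk = []
        else:
            chunk.append(p)
    if chunk:
        yield chunk


def write_corpus_files(out_dir, abstracts, entities, relations,
                       dialect: str = "plain") -> dict[str, Path]:
    """Write the three CHEMPROT-format TSVs; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / f"{name}.tsv"
             for name in ("abstracts", "entities", "relations")}
    with open(paths["abstracts"], "w", encoding="utf-8") as fh:
        for a in abstracts:
            fh.write(f"{a.doc_id}\t{a.title}\t{a.body}\n")
    kind_str = {EntityKind.CHEMICAL: "CHEMICAL", EntityKind.GENE: "GENE-Y"}
    with open(paths["entities"], "w", encoding="utf-8") as fh:
        for e in entities:
            fh.write(f"{e.doc_id}\t{e.entity_id}\t{kind_str[e.kind]}\t"
                     f"{e.char_start}\t{e.char_end}\t{e.surface}\n")
    from .corpus import write_predictions
    write_predictions(relations, paths["relations"], dialect=dialect)
    return paths


def generate_pretrain_text(n_lines: int, seed: int,
                           cfg: SynthConfig | None = None,
                           path=None) -> list[str]:
    """Lines from a first-order Markov grammar over the corpus inventory.

    Each token has three permitted successors with probabilities
    (0.7, 0.2, 0.1) — strongly non-uniform, so a uniformly substituted token
    is almost always implausible in context and the discrimination task is
    learnable.  Transition structure depends only on the lexicon seed;
    line sampling on ``seed``.
    """
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    cfg = cfg or SynthConfig()
    inventory = token_inventory(cfg)
    n = len(inventory)
    grammar_rng = np.random.default_rng(cfg.lexicon_seed + 1)
    successors = np.stack([grammar_rng.choice(n, size=3, replace=False)
                           for _ in range(n)])
    probs = np.array([0.7, 0.2, 0.1])

    rng = np.random.default_rng(seed)
    lines = []
    for _ in range(n_lines):
        length = int(rng.integers(8, 21))
        idx = int(rng.integers(0, n))
        toks = [inventory[idx]]
        for _ in range(length - 1):
            idx = int(successors[idx][rng.choice(3, p=probs)])
            toks.append(inventory[idx])
        lines.append(" ".join(toks))
    if path is not None:
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return lines


def generate_toy_glove(tokens, dim: int, seed: int, path=None) -> list[str]:
    """Text-format vector lines with seeded uniform [-1, 1] components."""
    if dim <= 0:
        raise ValueError("dim must be positive")
    rng = np.random.default_rng(seed)
    lines = []
    for tok in tokens:
        vec = rng.uniform(-1.0, 1.0, size=dim)
        lines.append(tok + " " + " ".join(f"{v:.5f}" for v in vec))
    if path is not None:
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return lines
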