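"""Reading and writing CHEMPROT-style corpus files and GloVe text vectors.

The corpus distribution uses three tab-separated files per split:

* abstracts: ``doc_id <TAB> title <TAB> body``
* entities:  ``doc_id <TAB> entity_id <TAB> type <TAB> start <TAB> end <TAB> surface``
* relations: ``doc_id <TAB> group <TAB> [Arg1:]chem_id <TAB> [Arg2:]gene_id``

Character offsets index into the document text, defined as
``title + "\\t" + body`` (0-based, half-open).  Strict mode verifies that each
entity's surface string equals the corresponding slice of the document text
and fails loudly on a different offset dialect.

Only the five evaluated relation groups (CPR:3,4,5,6,9) are retained on read;
records from other groups are dropped and counted in the log, mirroring how
the task discards them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Abstract", "EntityKind", "EntityMention", "CprGroup", "RelationGold",
    "GloveTable", "read_abstracts", "read_entities", "read_gold_relations",
    "write_predictions", "read_glove", "CorpusError",
]


class CorpusError(ValueError):
    """Raised for malformed or inconsistent corpus files."""


class EntityKind(Enum):
    CHEMICAL = "CHEMICAL"
    GENE = "GENE"


class CprGroup(Enum):
    """The five evaluated relation groups."""

    CPR3 = "CPR:3"   # upregulator / activator
    CPR4 = "CPR:4"   # downregulator / inhibitor
    CPR5 = "CPR:5"   # agonist
    CPR6 = "CPR:6"   # antagonist
    CPR9 = "CPR:9"   # substrate / product

    @property
    def label_index(self) -> int:
        """Class index in score vectors: 0 is NONE, then CPR:3,4,5,6,9."""
        return _GROUP_ORDER.index(self) + 1


_GROUP_ORDER = [CprGroup.CPR3, CprGroup.CPR4, CprGroup.CPR5,
                CprGroup.CPR6, CprGroup.CPR9]
GROUP_FOR_LABEL = {g.label_index: g for g in _GROUP_ORDER}


@dataclass(frozen=True)
class Abstract:
    doc_id: str
    title: str
    body: str

    @property
    def text(self) -> str:
        """Document text: title, one tab separator, body."""
        return self.title + "\t" + self.body


@dataclass(frozen=True)
class EntityMention:
    doc_id: str
    entity_id: str
    kind: EntityKind
    char_start: int
    char_end: int
    surface: str


@dataclass(frozen=True)
class RelationGold:
    doc_id: str
    group: CprGroup
    chem_id: str
    gene_id: str

    def tuple(self):
        return (self.doc_id, self.group, self.chem_id, self.gene_id)


class GloveTable:
    """Token -> dense vector mapping with a uniform dimension."""

    def __init__(self, dim: int):
        self.dim = dim
        self.vectors: dict[str, np.ndarray] = {}

    def __contains__(self, token):
        return token in self.vectors

    def __getitem__(self, token):
        return self.vectors[token]

    def __len__(self):
        return len(self.vectors)

    def add(self, token: str, vec: np.ndarray):
        if vec.shape != (self.dim,):
            raise CorpusError(
                f"vector for token {token!r} has dimension {vec.shape[0]}, "
                f"expected {self.dim}")
        self.vectors[token] = vec


def _lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if line.strip():
                yield lineno, line


def read_abstracts(path) -> list[Abstract]:
    """One abstract per line: ``doc_id <TAB> title <TAB> body``.

    Extra tabs are treated as part of the body.
    """
    out = []
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise CorpusError(
                f"{path}:{lineno}: expected >=3 tab-separated fields, "
                f"got {len(parts)}")
        out.append(Abstract(parts[0], parts[1], "\t".join(parts[2:])))
    return out


_ENTITY_TYPES = {
    "CHEMICAL": EntityKind.CHEMICAL,
    "GENE": EntityKind.GENE,
    "GENE-Y": EntityKind.GENE,   # normalisable / non-normalisable gene
    "GENE-N": EntityKind.GENE,   # mentions, both treated as GENE
}


def read_entities(path, abstracts=None, strict: bool = False) -> list[EntityMention]:
    """Read entity mentions; in strict mode verify offsets against the text.

    ``abstracts`` (required when ``strict``) is a list of
    :class:`Abstract` or a ``doc_id -> Abstract`` mapping.
    """
    doc_map = None
    if abstracts is not None:
        doc_map = (abstracts if isinstance(abstracts, dict)
                   else {a.doc_id: a for a in abstracts})
    if strict and doc_map is None:
        raise ValueError("strict entity reading requires the abstracts")
    out = []
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 6:
            raise CorpusError(
                f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
        doc_id, ent_id, etype, start, end, surface = parts[:6]
        if etype not in _ENTITY_TYPES:
            raise CorpusError(f"{path}:{lineno}: unknown entity type {etype!r}")
        try:
            cs, ce = int(start), int(end)
        except ValueError as exc:
            raise CorpusError(f"{path}:{lineno}: non-integer offset") from exc
        if not 0 <= cs < ce:
            raise CorpusError(
                f"{path}:{lineno}: invalid span [{cs}, {ce})")
        if strict:
            doc = doc_map.get(doc_id)
            if doc is None:
                raise CorpusError(f"{path}:{lineno}: unknown doc_id {doc_id!r}")
            piece = doc.text[cs:ce]
            if piece != surface:
                raise CorpusError(
                    f"{path}:{lineno}: offset convention mismatch for "
                    f"{ent_id} in {doc_id}: slice {piece!r} != surface "
                    f"{surface!r}")
        out.append(EntityMention(doc_id, ent_id, _ENTITY_TYPES[etype], cs, ce,
                                 surface))
    return out


def _strip_arg(ref: str, prefix: str) -> str:
    return ref[len(prefix):] if ref.startswith(prefix) else ref


def read_gold_relations(path, entities=None, strict: bool = False) -> list[RelationGold]:
    """Read gold relations, keeping only the five evaluated CPR groups.

    Lines carry ``doc_id, group, arg1, arg2`` where the arguments may use the
    challenge's ``Arg1:``/``Arg2:`` prefixes or be bare entity ids.  Records
    with other group labels (e.g. CPR:2) are silently dropped and counted in
    a log message.  With ``strict`` and an entity list, argument references
    must resolve to mentions of the right kind in the same document.
    """
    ent_map = None
    if entities is not None:
        ent_map = {(e.doc_id, e.entity_id): e for e in entities}
    valid = {g.value: g for g in CprGroup}
    out, dropped = [], 0
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 4:
            raise CorpusError(
                f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
        doc_id, group, a1, a2 = parts[:4]
        if group not in valid:
            dropped += 1
            continue
        chem_id = _strip_arg(a1, "Arg1:")
        gene_id = _strip_arg(a2, "Arg2:")
        if strict and ent_map is not None:
            for ent_id, kind in ((chem_id, EntityKind.CHEMICAL),
                                 (gene_id, EntityKind.GENE)):
                ent = ent_map.get((doc_id, ent_id))
                if ent is None:
                    raise CorpusError(
                        f"{path}:{lineno}: argument {ent_id!r} not found in "
                        f"entities of {doc_id}")
                if ent.kind is not kind:
                    raise CorpusError(
                        f"{path}:{lineno}: argument {ent_id!r} is "
                        f"{ent.kind.value}, expected {kind.value}")
        out.append(RelationGold(doc_id, valid[group], chem_id, gene_id))
    if dropped:
        logger.info("read_gold_relations: dropped %d record(s) from "
                    "non-evaluated groups", dropped)
    return out


def write_predictions(preds, path, dialect: str = "plain") -> None:
    """Write predicted relations as a CHEMPROT-style TSV.

    ``dialect='plain'`` writes bare entity ids (round-trips through
    :func:`read_gold_relations`); ``dialect='challenge'`` adds the
    ``Arg1:``/``Arg2:`` prefixes used by the official answer format.
    """
    if dialect not in ("plain", "challenge"):
        raise ValueError(f"unknown dialect {dialect!r}")
    p1, p2 = ("Arg1:", "Arg2:") if dialect == "challenge" else ("", "")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rel in preds:
            fh.write(f"{rel.doc_id}\t{rel.group.value}\t"
                     f"{p1}{rel.chem_id}\t{p2}{rel.gene_id}\n")


def read_glove(path, expected_dim: int | None = None) -> GloveTable:
    """Read text-format word vectors: one ``token v1 ... vd`` line each.

    The dimension is taken from the first line when ``expected_dim`` is None;
    any line with a different dimension raises an error naming the token.
    Later duplicates of a token overwrite earlier entries.
    """
    table = None
    for lineno, line in _lines(path):
        parts = line.split()
        token = parts[0]
        vals = parts[1:]
        if table is None:
            dim = expected_dim if expected_dim is not None else len(vals)
            table = GloveTable(dim)
        if len(vals) != table.dim:
            raise CorpusError(
                f"{path}:{lineno}: token {token!r} has {len(vals)} "
                f"components, expected {table.dim}")
        table.vectors[token] = np.array(vals, dtype=np.float64)
    if table is None:
        table = GloveTable(expected_dim if expected_dim is not None else 0)
    return table
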