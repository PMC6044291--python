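"""Chemistry-aware tokenization with character spans.

Chemical names are hostile to ordinary word tokenizers: hyphens, digits and
balanced brackets are part of the name ("COX-2", "(S)-ibuprofen"), while
sentence punctuation and unbalanced brackets are not.  The rule set here:

1. split on whitespace;
2. from each chunk, iteratively strip leading/trailing sentence punctuation
   (``. , ; : ! ? " '``) and leading/trailing brackets that are unbalanced
   within the chunk, emitting each stripped character as its own token;
3. keep everything else (internal hyphens, digits, balanced brackets) intact.

The tokenizer is a total function: token spans are non-overlapping, strictly
increasing, each surface equals the source slice, and the gaps between
consecutive spans contain only whitespace.  Callers needing a different
tokenizer can pass any ``text -> list[TokenSpan]`` callable wherever the
pipeline takes a ``tokenizer`` argument.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple

__all__ = ["TokenSpan", "tokenize_with_spans", "OverlapFlags",
           "overlap_flags", "span_overlap_flags"]

_WS_CHUNK = re.compile(r"\S+")
_STRIP_PUNCT = set(".,;:!?\"'")
_OPEN = {"(": ")", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}


@dataclass(frozen=True)
class TokenSpan:
    """A token with its 0-based half-open character span in the source text."""

    surface: str
    char_start: int
    char_end: int


def _balanced(s: str) -> bool:
    """True iff every bracket in ``s`` is matched (other chars ignored)."""
    stack = []
    for ch in s:
        if ch in _OPEN:
            stack.append(ch)
        elif ch in _CLOSE:
            if not stack or stack[-1] != _CLOSE[ch]:
                return False
            stack.pop()
    return not stack


def tokenize_with_spans(text: str) -> list[TokenSpan]:
    tokens: list[TokenSpan] = []
    for m in _WS_CHUNK.finditer(text):
        s, e = m.start(), m.end()
        prefix: list[TokenSpan] = []
        suffix: list[TokenSpan] = []
        while e - s > 1:
            chunk = text[s:e]
            first, last = chunk[0], chunk[-1]
            if first in _STRIP_PUNCT or (first in _OPEN and not _balanced(chunk)):
                prefix.append(TokenSpan(first, s, s + 1))
                s += 1
            elif last in _STRIP_PUNCT or (last in _CLOSE and not _balanced(chunk)):
                suffix.append(TokenSpan(last, e - 1, e))
                e -= 1
            else:
                break
        tokens.extend(prefix)
        if e > s:
            tokens.append(TokenSpan(text[s:e], s, e))
        tokens.extend(reversed(suffix))
    return tokens


class OverlapFlags(NamedTuple):
    """How a token span sits relative to an entity span."""

    inside: bool
    at_start: bool
    at_end: bool
    overlaps_start: bool
    overlaps_end: bool

    @property
    def any(self) -> bool:
        return any(self)


def span_overlap_flags(tok_start: int, tok_end: int,
                       ent_start: int, ent_end: int) -> OverlapFlags:
    inside = tok_start >= ent_start and tok_end <= ent_end
    return OverlapFlags(
        inside=inside,
        at_start=inside and tok_start == ent_start,
        at_end=inside and tok_end == ent_end,
        overlaps_start=(not inside) and tok_start < ent_start < tok_end,
        overlaps_end=(not inside) and tok_start < ent_end < tok_end,
    )


def overlap_flags(token: TokenSpan, entity) -> OverlapFlags:
    """Overlap of a token with anything exposing char_start/char_end."""
    return span_overlap_flags(token.char_start, token.char_end,
                              entity.char_start, entity.char_end)
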