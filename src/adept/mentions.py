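"""Locate ADE term hits inside clauses and create provisional mentions.

Every dictionary hit becomes exactly one mention, provisionally positive;
context assignment and refinement later decide the final status.  Mentions
found inside e-mail addresses, URLs or organisation names are still created
here and negated by the refinement stage, preserving the staged
architecture.
"""
from __future__ import annotations

from typing import List, Sequence

from .lexicon import Lexicon, match_terms
from .types import AdeStatus, Category, Clause, Mention, TermHit


def ade_hits(clause: Clause, text: str, lexicon: Lexicon) -> List[TermHit]:
    """ADE term hits in one clause, document-absolute offsets."""
    return match_terms(text[clause.start:clause.end], lexicon, Category.ADE,
                       offset=clause.start)


def detect_mentions(clauses: Sequence[Clause], text: str,
                    lexicon: Lexicon) -> List[Mention]:
    """One provisional-positive mention per ADE term hit, ordered by start."""
    mentions: List[Mention] = []
    for clause in clauses:
        for hit in ade_hits(clause, text, lexicon):
            mentions.append(Mention(
                doc_id=clause.doc_id, clause=clause,
                ade_concept=hit.entry.canonical,
                start=hit.start, end=hit.end,
                provisional_status=AdeStatus.POSITIVE))
    mentions.sort(key=lambda m: (m.start, m.end))
    return mentions
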