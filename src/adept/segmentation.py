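"""Sentence and clause segmentation.

Clinical narrative is predominantly short delimiter-separated clauses, and
the clause is the scope unit for every downstream decision: a trigger term
or refinement pattern can only affect a mention in its own clause.
Sentences split at sentence-final punctuation and line breaks; clauses
split at commas and semicolons; clauses that contain several ADE mentions
are further split immediately before termination terms (e.g. "but",
"however") so that each fragment carries a single event.
"""
from __future__ import annotations

import re
from typing import List, Sequence

from .lexicon import Lexicon, match_terms
from .types import (Category, Clause, ContextualSub, Sentence, SplitOrigin,
                    TermHit)

_ABBREVIATIONS = {"dr", "mr", "mrs", "ms", "prof", "rev", "st", "e.g",
                  "i.e", "etc", "vs", "cf", "approx", "dept", "eg", "ie"}

_TERMINATOR = re.compile(r"[.?!]+")


def _is_sentence_break(text: str, m: re.Match) -> bool:
    i, j = m.start(), m.end()
    # must be followed by whitespace or end of text (guards URLs, e-mails)
    if j < len(text) and not text[j].isspace():
        return False
    if text[i] == ".":
        # decimal number: digit on both sides
        if 0 < i < len(text) - 1 and text[i - 1].isdigit() \
                and text[j:j + 1].isdigit():
            return False
        # known abbreviation immediately before the period
        k = i
        while k > 0 and (text[k - 1].isalpha() or text[k - 1] == "."):
            k -= 1
        word = text[k:i].casefold().rstrip(".")
        if word in _ABBREVIATIONS:
            return False
    return True


def split_sentences(text: str, doc_id: str = "doc") -> List[Sentence]:
    """Split a document into sentence spans.

    Breaks occur at sentence-final ./?/! (with abbreviation and decimal
    guards) and at line breaks; every character belongs to at most one
    sentence.
    """
    sentences: List[Sentence] = []
    for line_m in re.finditer(r"[^\n]+", text):
        line_start = line_m.start()
        line = line_m.group(0)
        seg_start = 0
        for m in _TERMINATOR.finditer(line):
            if not _is_sentence_break(line, m):
                continue
            seg = line[seg_start:m.end()]
            if seg.strip():
                s0 = seg_start + len(seg) - len(seg.lstrip())
                sentences.append(Sentence(doc_id, line_start + s0,
                                          line_start + m.end()))
            seg_start = m.end()
        tail = line[seg_start:]
        if tail.strip():
            s0 = seg_start + len(tail) - len(tail.lstrip())
            e0 = seg_start + len(tail.rstrip())
            sentences.append(Sentence(doc_id, line_start + s0,
                                      line_start + e0))
    return sentences


_CLAUSE_DELIM = re.compile(r"[,;]")


def split_clauses(sentence: Sentence, text: str) -> List[Clause]:
    """Split a sentence at commas and semicolons.

    Commas inside numbers ("1,204") are not delimiters.  The clause spans
    partition the sentence's non-delimiter text; leading/trailing whitespace
    and terminal punctuation are excluded from each clause span.
    """
    stext = text[sentence.start:sentence.end]
    cuts = [0]
    for m in _CLAUSE_DELIM.finditer(stext):
        i = m.start()
        if stext[i] == "," and 0 < i < len(stext) - 1 \
                and stext[i - 1].isdigit() and stext[i + 1].isdigit():
            continue
        cuts.append(i)
    cuts.append(len(stext))
    had_delim = len(cuts) > 2
    clauses: List[Clause] = []
    for a, b in zip(cuts, cuts[1:]):
        seg = stext[a:b]
        core = seg.strip().strip(",;").rstrip(".?!").strip()
        if not core:
            continue
        s0 = a + _locate(seg, core)
        clauses.append(Clause(
            doc_id=sentence.doc_id, sentence=sentence,
            start=sentence.start + s0, end=sentence.start + s0 + len(core),
            split_origin=SplitOrigin.DELIMITER if had_delim
            else SplitOrigin.WHOLE_SENTENCE))
    return clauses


def _locate(segment: str, core: str) -> int:
    i = segment.find(core)
    if i < 0:  # cannot happen: core is derived from segment by stripping
        raise AssertionError("clause core not found in segment")
    return i


def split_multi_ade_clause(clause: Clause, mentions: Sequence[TermHit],
                           lexicon: Lexicon, text: str) -> List[Clause]:
    """Split a multi-ADE clause immediately before separating termination
    terms.

    `mentions` are ADE term hits with document-absolute offsets.  A
    termination term separates two hits when at least one hit ends before it
    and at least one starts after it.  Without a separating termination term
    the clause is returned unchanged.
    """
    if len(mentions) < 2:
        return [clause]
    ctext = text[clause.start:clause.end]
    term_hits = match_terms(ctext, lexicon, Category.CONTEXTUAL,
                            ContextualSub.TERMINATION.value,
                            offset=clause.start)
    cut_points = []
    for t in term_hits:
        before = any(m.end <= t.start for m in mentions)
        after = any(m.start >= t.end for m in mentions)
        if before and after:
            cut_points.append(t.start)
    if not cut_points:
        return [clause]
    bounds = [clause.start] + sorted(set(cut_points)) + [clause.end]
    out: List[Clause] = []
    for a, b in zip(bounds, bounds[1:]):
        seg = text[a:b]
        core = seg.strip()
        if not core:
            continue
        s0 = a + seg.find(core[0])
        out.append(Clause(doc_id=clause.doc_id, sentence=clause.sentence,
                          start=s0, end=s0 + len(core),
                          split_origin=SplitOrigin.TERMINATION_TERM))
    return out
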