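"""Independent brute-force oracles used to cross-check the scanners.

These deliberately share no code with the package: term matching is a
character-by-character scan over every start position; scope computation
walks right/left one character at a time until a termination-term offset.
"""
from typing import List, Sequence, Tuple


def _is_word(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def _match_at(text: str, i: int, surface: str, fold: bool) -> int:
    """Try to match `surface` at text[i:]; a single space in the surface
    matches one or more whitespace characters.  Returns the end offset or
    -1."""
    p = i
    for k, ch in enumerate(surface):
        if ch == " ":
            if p >= len(text) or not text[p].isspace():
                return -1
            while p < len(text) and text[p].isspace():
                p += 1
            continue
        if p >= len(text):
            return -1
        a, b = (text[p].casefold(), ch.casefold()) if fold else (text[p], ch)
        if a != b:
            return -1
        p += 1
    return p


def brute_force_hits(text: str, entries) -> List[Tuple[int, int, str]]:
    """All-substrings scan + greedy leftmost-longest non-overlap selection.

    Returns (start, end, surface) triples.
    """
    cands = []
    for e in entries:
        surface = " ".join(e.surface.split())
        fold = not e.case_sensitive
        for i in range(len(text)):
            if i > 0 and _is_word(text[i - 1]):
                continue
            end = _match_at(text, i, surface, fold)
            if end < 0:
                continue
            if end < len(text) and _is_word(text[end]):
                continue
            cands.append((i, end, e.surface))
    cands.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    chosen = []
    last_end = -1
    for s, e, surf in cands:
        if s >= last_end:
            chosen.append((s, e, surf))
            last_end = e
    return chosen


def brute_force_forward_scope(clause_start: int, clause_end: int,
                              trigger_end: int,
                              termination_spans: Sequence[Tuple[int, int]]
                              ) -> Tuple[int, int]:
    """Scan right from the trigger until the first termination-term start."""
    pos = trigger_end
    while pos < clause_end:
        if any(s == pos for s, _ in termination_spans):
            return (trigger_end, pos)
        pos += 1
    return (trigger_end, clause_end)


def brute_force_backward_scope(clause_start: int, clause_end: int,
                               trigger_start: int,
                               termination_spans: Sequence[Tuple[int, int]]
                               ) -> Tuple[int, int]:
    """Scan left from the trigger until the nearest termination-term end."""
    pos = trigger_start
    while pos > clause_start:
        if any(e == pos for _, e in termination_spans):
            return (pos, trigger_start)
        pos -= 1
    return (clause_start, trigger_start)
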