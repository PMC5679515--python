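"""Retention and removal refinement rules.

ConText alone misreads two recurring situations in clinical narrative:
negation whose object is not the event ("not taking his medication" — the
disorientation is real) and positive-looking mentions that are actually
warnings, monitoring plans, questionnaire items, uncertain findings or
parts of organisation names.  A declarative catalogue of retention rules
(keep positive despite negation cues) and removal rules (mark negative
despite the absence of negation) corrects both; retention overrides
removal, and both override the ConText assignment.

Token patterns are ordered sequences of dictionary-slot elements
(NEG, DRUG, ADE, HELP:<subcategory>), literal token alternations
(LIT:a|b|c) and bounded wildcards (GAP<=n, n ≤ 5 tokens); the catalogue is
shipped as a TSV resource so users can extend it.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .lexicon import Lexicon, match_terms
from .types import (Category, Clause, ContextAssignment, ContextualSub,
                    HelpingSub, Mention, NegationState, RefinementAction,
                    RefinementOutcome, TermHit)

_TOKEN_RE = re.compile(r"[A-Za-z0-9']+|[^\sA-Za-z0-9']")
_MAX_GAP = 5


@dataclass(frozen=True)
class RefinementRule:
    rule_id: str
    kind: str                 # "retention" | "removal"
    category: str             # catalogue category letter (A/B, a-d)
    pattern_type: str         # "tokens" | "regex" | "builtin"
    pattern: str
    must_contain_mention: bool
    description: str


@dataclass(frozen=True)
class RuleCatalogue:
    retention: Tuple[RefinementRule, ...]
    removal: Tuple[RefinementRule, ...]


def load_rules(path: Optional[Path] = None) -> RuleCatalogue:
    """Load the rule catalogue (bundled TSV by default), preserving order."""
    if path is None:
        path = Path(str(resources.files("adept") / "data" / "rules.tsv"))
    retention: List[RefinementRule] = []
    removal: List[RefinementRule] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            rule = RefinementRule(
                rule_id=row["rule_id"], kind=row["kind"],
                category=row["category"], pattern_type=row["pattern_type"],
                pattern=row["pattern"],
                must_contain_mention=row["must_contain_mention"] == "true",
                description=row["description"])
            if rule.pattern_type == "tokens":
                _parse_elements(rule.pattern)  # validate eagerly
            (retention if rule.kind == "retention" else removal).append(rule)
    return RuleCatalogue(tuple(retention), tuple(removal))


@lru_cache(maxsize=1)
def default_rules() -> RuleCatalogue:
    return load_rules()


# ------------------------------------------------------------ token matching
def _parse_elements(pattern: str) -> List[Tuple[str, object]]:
    """Parse a token pattern into (kind, payload) elements."""
    elements: List[Tuple[str, object]] = []
    for part in pattern.split():
        if part.startswith("GAP<="):
            n = int(part[5:])
            if not 0 <= n <= _MAX_GAP:
                raise ValueError(f"gap limit out of range in {pattern!r}")
            elements.append(("gap", n))
        elif part.startswith("LIT:"):
            alts = frozenset(a.casefold() for a in part[4:].split("|"))
            elements.append(("lit", alts))
        elif part.startswith("HELP:"):
            sub = HelpingSub(part[5:]).value
            elements.append(("hit", ("helping", sub)))
        elif part in ("NEG", "DRUG", "ADE"):
            label = {"NEG": ("contextual", "negation"),
                     "DRUG": ("drug", None),
                     "ADE": ("ade", None)}[part]
            elements.append(("hit", label))
        else:
            raise ValueError(f"unknown pattern element {part!r}")
    if not elements or elements[0][0] == "gap" or elements[-1][0] == "gap":
        raise ValueError(f"pattern must start/end with a concrete element: "
                         f"{pattern!r}")
    return elements


class ClauseView:
    """Tokenised clause with dictionary-slot tags, shared across rules."""

    def __init__(self, clause: Clause, text: str, lexicon: Lexicon):
        self.clause = clause
        self.text = text[clause.start:clause.end]
        self.offset = clause.start
        self.tokens = [(m.group(0), m.start(), m.end())
                       for m in _TOKEN_RE.finditer(self.text)]
        self._tok_by_start = {s: i for i, (_, s, _) in
                              enumerate(self.tokens)}
        self._tok_by_end = {e: i for i, (_, _, e) in enumerate(self.tokens)}
        self._hits: Dict[tuple, List[Tuple[int, int, int, int]]] = {}
        groups = [("contextual", ContextualSub.NEGATION.value),
                  ("drug", None), ("ade", None)]
        groups += [("helping", s.value) for s in HelpingSub]
        for cat, sub in groups:
            spans = []
            for h in match_terms(self.text, lexicon, Category(cat), sub):
                ti = self._tok_by_start.get(h.start)
                tj = self._tok_by_end.get(h.end)
                if ti is None or tj is None:
                    continue  # hit not aligned to token boundaries
                spans.append((ti, tj + 1, h.start, h.end))
            self._hits[(cat, sub)] = spans

    def hits(self, label: tuple) -> List[Tuple[int, int, int, int]]:
        return self._hits.get(label, [])

    def ade_spans(self) -> List[Tuple[int, int]]:
        return [(cs, ce) for _, _, cs, ce in self._hits[("ade", None)]]


def _match_tokens(view: ClauseView,
                  elements: Sequence[Tuple[str, object]]
                  ) -> Optional[Tuple[int, int]]:
    """First (leftmost) match of the element sequence; returns the matched
    character span within the clause, or None."""
    n_tok = len(view.tokens)

    def advance(idx: int, tok_pos: int, gap: Optional[int],
                span: Tuple[int, int]) -> Optional[Tuple[int, int]]:
        if idx == len(elements):
            return span
        kind, payload = elements[idx]
        if kind == "gap":
            return advance(idx + 1, tok_pos, int(payload), span)
        lo = tok_pos
        hi = n_tok if gap is None and idx == 0 else tok_pos + (gap or 0)
        for p in range(lo, min(hi, n_tok - 1) + 1):
            if kind == "lit":
                if p >= n_tok:
                    break
                tok, ts, te = view.tokens[p]
                if tok.casefold() in payload:
                    got = advance(idx + 1, p + 1, None,
                                  (min(span[0], ts), max(span[1], te)))
                    if got:
                        return got
            else:
                for ti, tj, cs, ce in view.hits(payload):
                    if ti == p:
                        got = advance(idx + 1, tj, None,
                                      (min(span[0], cs), max(span[1], ce)))
                        if got:
                            return got
        return None

    if n_tok == 0:
        return None
    # the first element floats anywhere; advance() anchors the rest
    got = advance(0, 0, None, (10 ** 9, -1))
    return got if got and got[1] >= 0 else None


# ----------------------------------------------------------------- builtins
_CAPS_WORD = re.compile(r"[A-Za-z][A-Za-z'-]*")


def _builtin_allcaps_run(view: ClauseView,
                         mention: Mention) -> Optional[Tuple[int, int]]:
    """Mention inside a run of >= 3 consecutive all-capital words."""
    words = [(m.group(0), m.start(), m.end())
             for m in _CAPS_WORD.finditer(view.text)]
    run: List[Tuple[str, int, int]] = []
    for w in words + [("", -1, -1)]:
        if w[0] and w[0].isupper() and len(w[0]) >= 2:
            run.append(w)
            continue
        if len(run) >= 3:
            rs, re_ = run[0][1], run[-1][2]
            m0 = mention.start - view.offset
            m1 = mention.end - view.offset
            if rs <= m0 and m1 <= re_:
                return (rs, re_)
        run = []
    return None


def _builtin_slash_menu(view: ClauseView,
                        mention: Mention) -> Optional[Tuple[int, int]]:
    """Two or more ADE hits separated only by a slash (symptom menu)."""
    spans = sorted(view.ade_spans())
    for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
        if re.fullmatch(r"\s*/\s*", view.text[e0:s1]):
            return (s0, e1)
    return None


_BUILTINS = {"allcaps_run": _builtin_allcaps_run,
             "slash_menu": _builtin_slash_menu}


# ------------------------------------------------------------- rule firing
def _fire(rule: RefinementRule, view: ClauseView,
          mention: Mention) -> Optional[Tuple[int, int]]:
    """Evaluate one rule against a clause/mention; returns the evidence
    span (document-absolute) if it fires."""
    if rule.pattern_type == "tokens":
        span = _match_tokens(view, _parse_elements(rule.pattern))
    elif rule.pattern_type == "regex":
        span = None
        for m in re.finditer(rule.pattern, view.text, re.IGNORECASE):
            if rule.must_contain_mention:
                m0 = mention.start - view.offset
                m1 = mention.end - view.offset
                if not (m.start() <= m0 and m1 <= m.end()):
                    continue
            span = (m.start(), m.end())
            break
    else:
        span = _BUILTINS[rule.pattern](view, mention)
    if span is None:
        return None
    return (span[0] + view.offset, span[1] + view.offset)


def apply_retention_rules(mention: Mention, context: ContextAssignment,
                          view: ClauseView,
                          catalogue: Optional[RuleCatalogue] = None
                          ) -> RefinementOutcome:
    """First retention rule matching the clause, in catalogue order.

    Every retention pattern contains a negation slot, so retention can only
    fire when negation vocabulary is present in the clause — the situation
    where ConText's negation priority overgeneralises.
    """
    catalogue = catalogue or default_rules()
    for rule in catalogue.retention:
        span = _fire(rule, view, mention)
        if span is not None:
            return RefinementOutcome(rule.rule_id,
                                     RefinementAction.RETAIN_POSITIVE, span)
    return RefinementOutcome()


def apply_removal_rules(mention: Mention, context: ContextAssignment,
                        view: ClauseView,
                        catalogue: Optional[RuleCatalogue] = None
                        ) -> RefinementOutcome:
    """First removal rule matching the clause, in catalogue order."""
    catalogue = catalogue or default_rules()
    for rule in catalogue.removal:
        span = _fire(rule, view, mention)
        if span is not None:
            return RefinementOutcome(rule.rule_id,
                                     RefinementAction.MARK_NEGATIVE, span)
    return RefinementOutcome()


def rule_category(catalogue: RuleCatalogue, rule_id: str) -> Optional[str]:
    for rule in catalogue.retention + catalogue.removal:
        if rule.rule_id == rule_id:
            return rule.category
    return None


def resolve(mention: Mention, retention: RefinementOutcome,
            removal: RefinementOutcome, context: ContextAssignment
            ) -> Tuple[NegationState, Optional[str]]:
    """Total override order: retention > removal > ConText.

    Returns the final negation state and the refinement rule applied (None
    when the ConText assignment stands).
    """
    if retention.fired:
        return NegationState.AFFIRMED, retention.rule_id
    if removal.fired:
        return NegationState.NEGATED, removal.rule_id
    return context.negation, None
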