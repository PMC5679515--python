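"""Extended ConText engine: clause-scoped contextual classification.

Each contextual trigger found in a mention's clause governs a scope:
forward triggers (most negation, possibility and hypothetical terms, e.g.
"no", "if") govern from the trigger to the first termination term or the
clause end; backward triggers (e.g. "was ruled out", "in the past") govern
from the clause start (or the nearest preceding termination term) back to
the trigger.  Scope never crosses a clause boundary.  A mention inside a
trigger's scope takes the value associated with the trigger; with several
triggers on one dimension the nearest wins (ties to the leftmost).  With no
trigger in scope the defaults apply: patient / affirmed / recent /
assertive.
"""
from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

from .lexicon import Lexicon, match_terms
from .types import (CategoricalValue, Category, Clause, ContextAssignment,
                    ContextualSub, Dimension, Direction, Experiencer,
                    Mention, NegationState, Temporality, TriggerHit)


def find_triggers(clause: Clause, text: str,
                  lexicon: Lexicon) -> List[TriggerHit]:
    """All contextual term hits in the clause, with direction and scope.

    Termination-term hits are returned with an empty scope: they only end
    the scopes of other triggers.
    """
    ctext = text[clause.start:clause.end]
    hits_by_sub = {
        sub: match_terms(ctext, lexicon, Category.CONTEXTUAL, sub.value,
                         offset=clause.start)
        for sub in ContextualSub
    }
    term_starts = sorted(h.start for h in
                         hits_by_sub[ContextualSub.TERMINATION])
    term_ends = sorted(h.end for h in
                       hits_by_sub[ContextualSub.TERMINATION])

    triggers: List[TriggerHit] = []
    for sub, hits in hits_by_sub.items():
        for h in hits:
            if sub is ContextualSub.TERMINATION:
                triggers.append(TriggerHit(h.entry, h.start, h.end,
                                           Direction.FORWARD,
                                           h.start, h.start))
                continue
            direction = h.entry.direction
            if direction is Direction.BACKWARD:
                scope_start = clause.start
                for e in term_ends:
                    if e <= h.start:
                        scope_start = max(scope_start, e)
                scope = (scope_start, h.start)
            else:
                scope_end = clause.end
                for s in term_starts:
                    if s >= h.end:
                        scope_end = min(scope_end, s)
                        break
                scope = (h.end, scope_end)
            triggers.append(TriggerHit(h.entry, h.start, h.end, direction,
                                       scope[0], scope[1]))
    triggers.sort(key=lambda t: (t.start, t.end))
    return triggers


def _in_scope(mention: Mention, t: TriggerHit) -> bool:
    return t.scope_start < mention.end and mention.start < t.scope_end


def _distance(mention: Mention, t: TriggerHit) -> int:
    if t.end <= mention.start:
        return mention.start - t.end
    if mention.end <= t.start:
        return t.start - mention.end
    return 0


def _nearest(mention: Mention,
             cands: Sequence[TriggerHit]) -> Optional[TriggerHit]:
    if not cands:
        return None
    return min(cands, key=lambda t: (_distance(mention, t), t.start))


def assign_context(mention: Mention,
                   triggers: Sequence[TriggerHit]) -> ContextAssignment:
    """Assign experiencer, negation, temporality and categorical value.

    Any in-scope negation trigger negates the mention (negation has a
    single non-default value, so nearest-wins is vacuous there; only the
    refinement rules may later override it).  The categorical value is set
    by the nearest in-scope trigger among possibility (general discussion),
    hypothetical and temporality (retrospective) triggers.
    """
    in_scope = [t for t in triggers
                if t.entry.subcategory != ContextualSub.TERMINATION.value
                and _in_scope(mention, t)]

    def of_sub(sub: ContextualSub, dim: Optional[Dimension] = None):
        return [t for t in in_scope
                if t.entry.subcategory == sub.value
                and (dim is None or t.entry.dimension is dim)]

    fired: List[TriggerHit] = []

    experiencer = Experiencer.PATIENT
    exp_t = _nearest(mention, of_sub(ContextualSub.EXPERIENCER))
    if exp_t is not None:
        experiencer = Experiencer.OTHER
        fired.append(exp_t)

    negation = NegationState.AFFIRMED
    neg_t = _nearest(mention, of_sub(ContextualSub.NEGATION))
    if neg_t is not None:
        negation = NegationState.NEGATED
        fired.append(neg_t)

    temporality = Temporality.RECENT
    temp_t = _nearest(mention, of_sub(ContextualSub.TEMPORALITY_HYPOTHETICAL,
                                      Dimension.TEMPORALITY))
    if temp_t is not None:
        temporality = Temporality.HISTORICAL
        fired.append(temp_t)

    categorical = CategoricalValue.ASSERTIVE
    cat_cands: List[Tuple[TriggerHit, CategoricalValue]] = []
    for t in of_sub(ContextualSub.POSSIBILITY):
        cat_cands.append((t, CategoricalValue.GENERAL_DISCUSSION))
    for t in of_sub(ContextualSub.TEMPORALITY_HYPOTHETICAL,
                    Dimension.HYPOTHETICAL):
        cat_cands.append((t, CategoricalValue.HYPOTHETICAL))
    for t in of_sub(ContextualSub.TEMPORALITY_HYPOTHETICAL,
                    Dimension.TEMPORALITY):
        cat_cands.append((t, CategoricalValue.RETROSPECTIVE))
    if cat_cands:
        best = min(cat_cands,
                   key=lambda tv: (_distance(mention, tv[0]), tv[0].start))
        categorical = best[1]
        if best[0] not in fired:
            fired.append(best[0])

    return ContextAssignment(
        experiencer=experiencer, negation=negation, temporality=temporality,
        categorical_value=categorical,
        triggers_fired=tuple(t.entry.surface for t in fired))
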