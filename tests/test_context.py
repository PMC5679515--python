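"""Clause-scoped trigger detection and context assignment."""
import random

from adept import (assign_context, find_triggers, split_clauses,
                   split_sentences, detect_mentions)
from adept.types import (CategoricalValue, ContextualSub, Direction,
                         Experiencer, NegationState, Temporality)

from _oracles import brute_force_backward_scope, brute_force_forward_scope


def _setup(text, lexicon):
    [sentence] = split_sentences(text)
    [clause] = split_clauses(sentence, text)
    triggers = find_triggers(clause, text, lexicon)
    mentions = detect_mentions([clause], text, lexicon)
    return clause, triggers, mentions


class TestFindTriggers:
    def test_forward_negation_scope_covers_rest_of_clause(self, lexicon):
        text = "No complaints of dizziness"
        clause, triggers, mentions = _setup(text, lexicon)
        negs = [t for t in triggers
                if t.entry.subcategory == ContextualSub.NEGATION.value]
        assert len(negs) == 1
        t = negs[0]
        assert t.direction is Direction.FORWARD
        assert (t.scope_start, t.scope_end) == (t.end, clause.end)
        m = mentions[0]
        assert t.scope_start <= m.start and m.end <= t.scope_end

    def test_no_contextual_terms_gives_no_triggers(self, lexicon):
        _, triggers, _ = _setup("headache", lexicon)
        assert triggers == []

    def test_termination_term_ends_forward_scope(self, lexicon):
        text = "no nausea however vomiting"
        clause, triggers, mentions = _setup(text, lexicon)
        neg = [t for t in triggers
               if t.entry.subcategory == ContextualSub.NEGATION.value][0]
        term = [t for t in triggers
                if t.entry.subcategory ==
                ContextualSub.TERMINATION.value][0]
        assert neg.scope_end == term.start
        vomiting = [m for m in mentions if m.ade_concept == "vomiting"][0]
        assert not (neg.scope_start < vomiting.end
                    and vomiting.start < neg.scope_end)

    def test_backward_trigger_scope_reaches_clause_start(self, lexicon):
        text = "nausea was ruled out"
        clause, triggers, mentions = _setup(text, lexicon)
        neg = [t for t in triggers
               if t.entry.subcategory == ContextualSub.NEGATION.value][0]
        assert neg.direction is Direction.BACKWARD
        assert (neg.scope_start, neg.scope_end) == (clause.start, neg.start)

    def test_scope_never_crosses_clause_boundary(self, lexicon):
        text = "denies nausea, reports headache"
        [sentence] = split_sentences(text)
        clauses = split_clauses(sentence, text)
        assert len(clauses) == 2
        for c in clauses:
            for t in find_triggers(c, text, lexicon):
                assert c.start <= t.scope_start <= t.scope_end <= c.end


class TestAssignContext:
    def test_in_scope_negation_negates(self, lexicon):
        _, triggers, mentions = _setup("No complaints of dizziness",
                                       lexicon)
        ctx = assign_context(mentions[0], triggers)
        assert ctx.negation is NegationState.NEGATED
        assert ctx.triggers_fired

    def test_defaults_without_triggers(self, lexicon):
        _, triggers, mentions = _setup("headache", lexicon)
        ctx = assign_context(mentions[0], triggers)
        assert (ctx.experiencer, ctx.negation, ctx.temporality,
                ctx.categorical_value) == (
            Experiencer.PATIENT, NegationState.AFFIRMED, Temporality.RECENT,
            CategoricalValue.ASSERTIVE)
        assert ctx.triggers_fired == ()

    def test_three_dimensions_fire_independently(self, lexicon):
        text = "his mother had no nausea in the past"
        _, triggers, mentions = _setup(text, lexicon)
        ctx = assign_context(mentions[0], triggers)
        assert ctx.experiencer is Experiencer.OTHER
        assert ctx.negation is NegationState.NEGATED
        assert ctx.temporality is Temporality.HISTORICAL

    def test_hypothetical_trigger_sets_categorical_value(self, lexicon):
        _, triggers, mentions = _setup("if dizziness develops", lexicon)
        ctx = assign_context(mentions[0], triggers)
        assert ctx.categorical_value is CategoricalValue.HYPOTHETICAL

    def test_temporality_trigger_sets_retrospective(self, lexicon):
        _, triggers, mentions = _setup("previously experienced nausea",
                                       lexicon)
        ctx = assign_context(mentions[0], triggers)
        assert ctx.temporality is Temporality.HISTORICAL
        assert ctx.categorical_value is CategoricalValue.RETROSPECTIVE

    def test_possibility_trigger_sets_general_discussion(self, lexicon):
        _, triggers, mentions = _setup("possible nausea", lexicon)
        ctx = assign_context(mentions[0], triggers)
        assert ctx.categorical_value is CategoricalValue.GENERAL_DISCUSSION

    def test_out_of_scope_trigger_changes_nothing(self, lexicon):
        # negation scope is cut by "however": vomiting stays affirmed
        _, triggers, mentions = _setup("no nausea however vomiting",
                                       lexicon)
        vomiting = [m for m in mentions if m.ade_concept == "vomiting"][0]
        ctx = assign_context(vomiting, triggers)
        assert ctx.negation is NegationState.AFFIRMED
        nausea = [m for m in mentions if m.ade_concept == "nausea"][0]
        assert assign_context(nausea, triggers).negation is \
            NegationState.NEGATED


class TestScopeOracle:
    def test_scopes_match_brute_force_on_random_clauses(self, lexicon):
        rng = random.Random(20260930)
        vocab = ["no", "denies", "if", "previously", "mother", "however",
                 "but", "nausea", "dizziness", "stable", "today", "calm",
                 "was", "ruled", "out", "reports"]
        checked = 0
        for _ in range(400):
            text = " ".join(rng.choice(vocab)
                            for _ in range(rng.randint(1, 12)))
            sentences = split_sentences(text)
            if not sentences:
                continue
            [sentence] = sentences
            for clause in split_clauses(sentence, text):
                triggers = find_triggers(clause, text, lexicon)
                term_spans = [(t.start, t.end) for t in triggers
                              if t.entry.subcategory ==
                              ContextualSub.TERMINATION.value]
                for t in triggers:
                    if t.entry.subcategory == \
                            ContextualSub.TERMINATION.value:
                        continue
                    if t.direction is Direction.BACKWARD:
                        expected = brute_force_backward_scope(
                            clause.start, clause.end, t.start, term_spans)
                    else:
                        expected = brute_force_forward_scope(
                            clause.start, clause.end, t.end, term_spans)
                    assert (t.scope_start, t.scope_end) == expected
                    checked += 1
        assert checked >= 300
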