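"""Retention/removal rule catalogue: size, per-rule fixtures, override
order."""
import itertools

import pytest

from adept import (apply_removal_rules, apply_retention_rules,
                   detect_mentions, resolve, split_clauses,
                   split_sentences)
from adept.refinement import ClauseView, _fire
from adept.types import (ContextAssignment, NegationState, RefinementAction,
                         RefinementOutcome)

# rule_id -> (clause where the rule's pattern fires,
#             near-miss clause where it does not)
FIXTURES = {
    "RET-01": ("no relief from headache", "relief from headache"),
    "RET-02": ("disorientated and not taking his medication",
               "disorientated and taking his medication"),
    "RET-03": ("agitated and non compliant with medication",
               "agitated and compliant with medication"),
    "RET-04": ("no increase in headache", "increase in headache"),
    "RET-05": ("no change in restlessness", "change in restlessness"),
    "RET-06": ("restless and not taking", "restless and taking"),
    "RET-07": ("restlessness has not worsened", "restlessness worsened"),
    "RET-08": ("headache not improved", "headache improved"),
    "RET-09": ("dizzy and not on olanzapine", "dizzy on olanzapine"),
    "REM-01": ("olanzapine explained as it can cause weight gain",
               "olanzapine helping with weight gain"),
    "REM-02": ("as it can cause weight gain", "weight gain recorded"),
    "REM-03": ("warned ZZZZ of dizziness", "dizziness reported"),
    "REM-04": ("myocarditis screen", "myocarditis confirmed"),
    "REM-05": ("risk of seizures", "seizures occurred"),
    "REM-06": ("discussed side effects such as nausea",
               "reported side effects of nausea"),
    "REM-07": ("possible side effects include nausea",
               "side effects include nausea"),
    "REM-08": ("ongoing investigation for myocarditis",
               "investigation complete for myocarditis"),
    "REM-09": ("ecg requested for tachycardia",
               "ecg normal and tachycardia resolved"),
    "REM-10": ("information leaflet given about nausea",
               "leaflet describes nausea"),
    "REM-11": ("warning about possible dizziness",
               "dizziness without prior notice"),
    "REM-12": ("seizure precautions in place", "seizures observed"),
    "REM-13": ("unstable partial complex seizures", "frequent seizures"),
    "REM-14": ("seizures of unclear significance", "seizures continuing"),
    "REM-15": ("query seizures", "seizures today"),
    "REM-16": ("?seizures noted", "seizures noted"),
    "REM-17": ("seizures ?cause unknown", "seizures cause unknown"),
    "REM-18": ("cannot exclude myocarditis", "myocarditis excluded"),
    "REM-19": ("Fainting/ dizziness *No * Yes", "Fainting/ dizziness here"),
    "REM-20": ("Do you feel dizziness: Yes/No", "Do you feel dizziness"),
    "REM-21": ("dizziness x 5", "dizziness for 5 days"),
    "REM-22": ("dizziness [ ]", "dizziness [severe]"),
    "REM-23": ("Fainting/ dizziness", "Fainting and dizziness"),
    "REM-24": ("contact sjs@sydenham.lewisham.sch.uk today",
               "contact team@clinic.nhs.uk about sjs"),
    "REM-25": ("see www.nhs.uk/Conditions/Anxiety now",
               "see www.nhs.uk/Conditions now regarding anxiety"),
    "REM-26": ("CENTRE FOR ANXIETY DISORDERS AND TRAUMA",
               "Centre for Anxiety Disorders"),
}


def _view_and_mention(text, lexicon):
    [sentence] = split_sentences(text)
    clause = split_clauses(sentence, text)[0]
    view = ClauseView(clause, text, lexicon)
    mentions = detect_mentions([clause], text, lexicon)
    assert mentions, f"fixture clause has no ADE mention: {text!r}"
    return view, mentions[0]


def _rule(rules, rule_id):
    return {r.rule_id: r for r in rules.retention + rules.removal}[rule_id]


class TestCatalogue:
    def test_exactly_9_retention_and_26_removal_rules(self, rules):
        assert len(rules.retention) == 9
        assert len(rules.removal) == 26
        ids = [r.rule_id for r in rules.retention + rules.removal]
        assert len(set(ids)) == 35

    def test_every_rule_has_fixtures(self, rules):
        assert set(FIXTURES) == {r.rule_id for r in
                                 rules.retention + rules.removal}

    @pytest.mark.parametrize("rule_id", sorted(FIXTURES))
    def test_rule_fires_on_its_fixture(self, rule_id, rules, lexicon):
        rule = _rule(rules, rule_id)
        pos, neg = FIXTURES[rule_id]
        view, mention = _view_and_mention(pos, lexicon)
        span = _fire(rule, view, mention)
        assert span is not None
        # evidence lies inside the mention's clause and is non-empty
        assert view.clause.start <= span[0] < span[1] <= view.clause.end

    @pytest.mark.parametrize("rule_id", sorted(FIXTURES))
    def test_rule_silent_on_near_miss(self, rule_id, rules, lexicon):
        rule = _rule(rules, rule_id)
        pos, neg = FIXTURES[rule_id]
        view, mention = _view_and_mention(neg, lexicon)
        assert _fire(rule, view, mention) is None


class TestApplication:
    def test_first_matching_removal_rule_wins(self, rules, lexicon):
        view, mention = _view_and_mention("warned ZZZZ of dizziness",
                                          lexicon)
        out = apply_removal_rules(mention, ContextAssignment(), view, rules)
        assert out.rule_id == "REM-03"
        assert out.action is RefinementAction.MARK_NEGATIVE

    def test_retention_fires_on_drug_administration_negation(self, rules,
                                                             lexicon):
        text = "ZZZZZ appeared to be disorientated and not taking his " \
               "medication"
        view, mention = _view_and_mention(text, lexicon)
        out = apply_retention_rules(mention, ContextAssignment(), view,
                                    rules)
        assert out.action is RefinementAction.RETAIN_POSITIVE

    def test_retention_silent_without_negation_vocabulary(self, rules,
                                                          lexicon):
        view, mention = _view_and_mention("reports ongoing nausea today",
                                          lexicon)
        out = apply_retention_rules(mention, ContextAssignment(), view,
                                    rules)
        assert out.action is RefinementAction.NONE
        assert out.rule_id is None

    def test_removal_silent_on_plain_affirmation(self, rules, lexicon):
        view, mention = _view_and_mention("reports ongoing nausea today",
                                          lexicon)
        out = apply_removal_rules(mention, ContextAssignment(), view, rules)
        assert out.action is RefinementAction.NONE


class TestResolve:
    RET = RefinementOutcome("RET-02", RefinementAction.RETAIN_POSITIVE,
                            (0, 5))
    REM = RefinementOutcome("REM-03", RefinementAction.MARK_NEGATIVE,
                            (0, 5))
    NONE = RefinementOutcome()

    def test_override_order_is_total(self, lexicon):
        """Exhaustive truth table: retention > removal > ConText."""
        view, mention = _view_and_mention("nausea", lexicon)
        for ret, rem, neg in itertools.product(
                [self.RET, self.NONE], [self.REM, self.NONE],
                [NegationState.AFFIRMED, NegationState.NEGATED]):
            ctx = ContextAssignment(negation=neg)
            final, rule_id = resolve(mention, ret, rem, ctx)
            if ret.fired:
                assert final is NegationState.AFFIRMED
                assert rule_id == ret.rule_id
            elif rem.fired:
                assert final is NegationState.NEGATED
                assert rule_id == rem.rule_id
            else:
                assert final is neg
                assert rule_id is None

    def test_outcome_invariant_rule_id_iff_action(self):
        with pytest.raises(ValueError):
            RefinementOutcome("RET-01", RefinementAction.NONE, None)
        with pytest.raises(ValueError):
            RefinementOutcome(None, RefinementAction.MARK_NEGATIVE, (0, 1))
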