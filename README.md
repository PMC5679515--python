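# adept

Rule-based detection and classification of **adverse drug event (ADE)
mentions** in free-text clinical notes, aimed at pharmacovigilance work on
psychiatric electronic health records, where most ADE information lives in
short, noisy narrative ("No complaints of dizziness", "warned ZZZZZ of
dizziness", "Fainting/ dizziness \*No \* Yes").

## What it does

Clinical narrative is mostly short delimiter-separated clauses, each about
one episode, but it is saturated with context that flips the meaning of a
mention: negation, hypothetical advice, family history, warnings and
monitoring plans, questionnaire fragments, even organisation names. The
pipeline therefore:

1. **Segments** documents into sentences and comma/semicolon-bounded
   clauses, and re-splits multi-ADE clauses at termination terms ("but",
   "however") so each fragment carries one event.
2. **Detects mentions** of dictionary-defined ADE terms (longest-match,
   word-boundary gazetteer over curated surface forms such as *drowsy* →
   `sedation`).
3. **Assigns context** with a clause-scoped, extended ConText engine:
   trigger terms (negation, possibility, experiencer, temporality &
   hypothetical, termination) govern forward or backward scopes that never
   cross a clause boundary; each mention receives `experiencer`
   (patient/other), `negation` (affirmed/negated), `temporality`
   (recent/historical) and `categorical_value`
   (assertive/hypothetical/retrospective/general_discussion).
4. **Refines** with a declarative catalogue of 9 *retention* rules (keep a
   mention positive despite negation cues — "not taking his medication",
   "has not worsened") and 26 *removal* rules (mark negative despite no
   negation — warnings/monitoring, uncertainty, questionnaires,
   e-mails/URLs/ALL-CAPS names). Retention overrides removal overrides
   ConText.
5. **Emits** one annotation per mention with the final
   `ade_status = positive` iff patient ∧ affirmed ∧ recent ∧ assertive,
   as JSONL or BRAT standoff.

An **evaluation harness** pairs predictions with gold annotations by
(document, concept, overlapping span) and reports precision P = TP/(TP+FP),
sensitivity R = TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/N and F = 2PR/(P+R). A **seeded synthetic-note generator**
fabricates pseudo-clinical corpora with gold labels across all the context
categories (≈5% multi-ADE clauses by default), so the whole system is
testable without any patient data.

## Worked example

```python
from adept import annotate_document

text = ("He did not complain of constipation. "
        "The patient is still suffering from a light headache.")
for a in annotate_document(text, doc_id="note-1"):
    print(a.to_dict())
```

prints (abridged):

```json
{"ade_type": "constipation", "negation": "negated",  "ade_status": "negative",
 "clause": "He did not complain of constipation", "start": 23, "end": 35, ...}
{"ade_type": "headache",     "negation": "affirmed", "ade_status": "positive",
 "clause": "The patient is still suffering from a light headache",
 "start": 81, "end": 89, ...}
```

Sentence/clause scoping is what keeps "did not" from spilling onto the
headache: with paragraph-wide scope both mentions would be negated.

From the shell:

```bash
adept synth --n-docs 30 --seed 4 --out corpus        # synthetic notes + gold
adept annotate --input corpus --output pred.jsonl    # run the pipeline
adept evaluate --gold corpus/gold.jsonl --pred pred.jsonl
```

the last command printing, on this clean corpus:

```json
{"tp": 65, "fp": 0, "tn": 138, "fn": 0, "precision": 1.0, "sensitivity": 1.0,
 "specificity": 1.0, "accuracy": 1.0, "f_measure": 1.0}
```

## Layout

- `src/adept/` — `lexicon`, `segmentation`, `mentions`, `context`,
  `refinement`, `pipeline`, `evaluation`, `synthetic`, `cli`
- `src/adept/data/` — bundled dictionaries (four categories; contextual
  triggers in five subcategories) and the refinement-rule catalogue
  (`rules.tsv`, user-extensible)
- `docs/methods.md` — the model, its assumptions and design choices
- `tests/` — unit, property and acceptance suites
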