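# Methods

## The annotation model

The package treats ADE annotation as staged rule application over
clause-scoped text, resting on two assumptions about clinical narrative:

1. **Clauses are the semantic unit.** Notes are mostly short clauses
   bounded by periods, commas and semicolons, each conveying one
   ADE-related episode. All context resolution is therefore confined to
   the clause containing the mention; a trigger term never affects a
   mention in another clause. Clauses containing several ADE terms
   (roughly 5% before splitting) are further divided immediately before
   termination terms ("but", "however") that separate two ADE hits, so
   fragments carry one event each. If no termination term separates the
   hits the clause is left intact and all its mentions share one scope.
2. **Context decides status.** A detected ADE term is only provisionally
   positive. Four clause-scoped features — experiencer, negation,
   temporality, categorical value — are assigned from trigger vocabulary,
   then corrected by refinement rules; the final status is the pure
   function *positive ⇔ patient ∧ affirmed ∧ recent ∧ assertive*.

## Dictionaries

Four bundled TSV tables drive everything (all user-replaceable through
`load_lexicon`):

- **ADE terms**: 26 concepts (the 19 evaluation concepts plus concepts
  needed by the worked examples: headache, restlessness, anxiety,
  seizures, fainting, disorientation, vomiting) with 94 surface forms
  including variants and common misspellings.
- **Drug terms**: 58 psychotropic drug names, classes and generic words
  ("medication", "depot").
- **Helping terms**: 138 surfaces in five subcategories — occurrence,
  administration, monitoring, negative_effect, drug_link — consumed by
  the refinement patterns.
- **Contextual triggers**: 710 surfaces in five subcategories with fixed
  sizes (experiencer 75, negation 413, possibility 44, termination 106,
  temporality & hypothetical 72). Temporality & hypothetical is one
  dictionary subcategory but two assignment dimensions; each entry
  carries a `dimension` flag because the output separates `temporality`
  from `categorical_value`.

Matching is case-insensitive (clinical notes mix cases) with a per-entry
`case_sensitive` flag for acronyms like "SE"/"EPSE"; policy is
leftmost-longest, non-overlapping, at word boundaries, with internal
whitespace in multi-word surfaces matching any whitespace run. The same
scanner is verified against an independent all-substrings brute-force
oracle in the tests.

"Patient"-like subject words are deliberately absent from the experiencer
table: experiencer triggers encode *other* subjects, and patient is the
default.

## Context engine

Forward triggers govern from the trigger to the first termination term or
the clause end; a small closed set of backward triggers ("was ruled out",
"in the past", "as a child") governs from the clause start (or nearest
preceding termination term) back to the trigger. Within a dimension the
nearest in-scope trigger wins, ties to the leftmost; negation has a single
non-default value, so any in-scope negation trigger negates — only
refinement can override that. A temporality trigger sets
temporality=historical and categorical_value=retrospective; hypothetical
triggers set categorical_value=hypothetical; possibility triggers set
general_discussion. When hypothetical and retrospective candidates both
cover a mention the nearest trigger decides the categorical value — the
precedence is genuinely ambiguous, so the choice is the generic
nearest-wins rule rather than a special case.

## Refinement catalogue

`data/rules.tsv` registers exactly 9 retention and 26 removal rules, each
traceable to a behaviour category (retention A: negation of drug
administration; retention B: negation of a change of state; removal a:
warnings/monitoring/explanations; b: uncertainty; c: questionnaires; d:
surface contexts — e-mails, URLs, ALL-CAPS organisation names). Patterns
are ordered element sequences over dictionary slots, literal alternations
and gap wildcards capped at 5 tokens, plus a few regex/builtin detectors
(checkbox pairs, trailing "x N" scores, slash menus, e-mail/URL, a run of
≥3 consecutive all-capital words — the threshold that catches
"CENTRE FOR ANXIETY DISORDERS AND TRAUMA" without firing on acronym
pairs). First match wins inside each catalogue, ordered by specificity;
retention > removal > ConText is a total override order, tested
exhaustively.

Two interpretation points, decided once:

- Retention is pattern-driven rather than gated on the mention already
  being ConText-negated: in the canonical retention situations
  ("disorientated and not taking his medication", "restlessness has not
  worsened") the negation lies *after* the mention, so a forward-scope
  engine never negates the mention in the first place and a strict gate
  would make the rules dead code. Every retention pattern contains a
  negation slot, so retention still cannot fire in negation-free clauses.
- Uncertainty removals (category b) set status negative *and* record
  categorical_value=general_discussion, treating an uncertain finding as
  discussion rather than a negated fact.

Because rule evidence must lie inside the mention's clause, in "She has
had 4 seizures within the last 2 weeks, unstable partial complex
seizures" only the second mention (beside "unstable") is removed; the
first clause reads as a positive event report and stays positive.

## Evaluation

Predictions pair with gold by (document, concept, span overlap), greedy
left-to-right. Exact-span pairs score TP/TN/FP/FN from the two statuses;
a *partial* overlap with conflicting statuses resolves to TN (the
conservative reading of partial matches), switchable off via
`partial_conflict_to_negative`. Unpaired gold positives are FN, unpaired
gold negatives TN, unpaired predicted positives FP; unpaired predicted
negatives assert nothing and are not scored. Zero-denominator ratios are
NaN, never 0; values are rounded only in the presentation table (2 d.p.).

## Synthetic corpus

The generator emulates short psychiatric progress notes: 1–30 sentences
per document grouped into 1–4-sentence paragraphs, patient names masked
"ZZZZZ", ~30% contentless filler sentences, and mention-bearing sentences
drawn from a category mix (defaults: affirmed .30, negated .25,
hypothetical .08, historical .08, other-experiencer .07,
warning/monitoring .10, questionnaire .05, organisation/e-mail .02,
uncertainty .05) with a 5% multi-ADE clause rate, matching the observed
frequency of multi-ADE clauses in real notes. Affirmed draws include
retention-situation templates (still positive). Fourteen canonical
fixture documents — the worked examples above — are always emitted first
so regression tests can pin them. Gold status is implied by the template
category; every insertion is logged with exact offsets. Typo injection
(default rate 0) swaps interior characters of tokens that are neither
dictionary vocabulary nor inside gold spans, preserving length so offsets
stay valid.

What passing means — and does not mean: with typo_rate=0 the pipeline
scores accuracy 1.0 on this corpus because generator templates exercise
exactly the catalogued phenomena; that demonstrates internal soundness
(generator and pipeline share only the dictionary), not performance on
real clinical text, whose vocabulary, typos and layout are far messier.
The paragraph-vs-clause comparison on the same corpus shows the expected
one-sided relationship: paragraph-wide scope loses ~15% of mentions to
scope bleed-through while every paragraph-correct mention remains correct
under clause scope.

## Numerical and degenerate-input choices

- Offsets are 0-based, half-open, document-absolute everywhere.
- Sentence splitting guards decimals ("2.5 mg"), common abbreviations and
  periods not followed by whitespace (URLs, e-mails); line breaks end
  sentences. Commas split clauses unconditionally except between digits
  ("1,204"); slashes are not delimiters, keeping symptom menus together.
- Empty text, pure punctuation and over-long lines annotate to empty or
  short lists without raising.
- Duplicate dictionary rows collapse with a logged warning; an
  empty-after-header category file is a validation error.
- Problem sizes in the acceptance script (500 synthetic documents, ~1,100
  random oracle instances) are chosen to give tight binomial error on the
  5% multi-ADE calibration while keeping a full run in seconds.

## Known limitations

- No POS tagging or parsing; the rules never need them.
- No fuzzy matching or concept normalisation beyond listed variants;
  implied ADEs ("cannot fit in his clothes") are covered only as far as
  surface forms are listed.
- Coverage of precautionary phrasings around rare, severe events is
  bounded by the catalogued removal categories.
- Section headers ("Family History:") and cross-sentence coreference are
  out of scope; scope is strictly clause-local.
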