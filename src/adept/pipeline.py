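"""End-to-end annotation: segmentation → mention detection → context →
refinement → final annotations, plus JSONL and BRAT standoff writers.

A mention's final status is a pure function of its four contextual
features after refinement: it is positive iff the experiencer is the
patient, negation resolves affirmed, the event is recent and the
categorical value is assertive.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .context import assign_context, find_triggers
from .lexicon import Lexicon, default_lexicon
from .mentions import ade_hits, detect_mentions
from .refinement import (ClauseView, RuleCatalogue, apply_removal_rules,
                         apply_retention_rules, default_rules, resolve,
                         rule_category)
from .segmentation import split_clauses, split_multi_ade_clause, \
    split_sentences
from .types import (AdeStatus, Annotation, CategoricalValue, Clause,
                    ContextAssignment, Experiencer, GoldAnnotation, Mention,
                    NegationState, Sentence, SplitOrigin, Temporality)

_PARAGRAPH_RE = re.compile(r"[^\n]+(?:\n(?!\s*\n)[^\n]*)*")


def derive_status(experiencer: Experiencer, negation: NegationState,
                  temporality: Temporality,
                  categorical_value: CategoricalValue) -> AdeStatus:
    """Positive iff patient / affirmed / recent / assertive."""
    if (experiencer is Experiencer.PATIENT
            and negation is NegationState.AFFIRMED
            and temporality is Temporality.RECENT
            and categorical_value is CategoricalValue.ASSERTIVE):
        return AdeStatus.POSITIVE
    return AdeStatus.NEGATIVE


def _paragraph_units(text: str, doc_id: str) -> List[Clause]:
    units = []
    for m in _PARAGRAPH_RE.finditer(text):
        seg = m.group(0)
        core = seg.strip()
        if not core:
            continue
        s0 = m.start() + seg.find(core[0])
        sent = Sentence(doc_id, s0, s0 + len(core))
        units.append(Clause(doc_id, sent, s0, s0 + len(core),
                            SplitOrigin.WHOLE_SENTENCE))
    return units


def _sentence_units(text: str, doc_id: str) -> List[Clause]:
    units = []
    for s in split_sentences(text, doc_id):
        core = text[s.start:s.end].rstrip(".?! \t")
        end = s.start + len(core)
        if end > s.start:
            units.append(Clause(doc_id, s, s.start, end,
                                SplitOrigin.WHOLE_SENTENCE))
    return units


def segment(text: str, doc_id: str, lexicon: Lexicon,
            boundary_mode: str = "clause") -> List[Clause]:
    """Produce the annotation-scope units for a document.

    boundary_mode: "clause" (default; delimiter clauses with multi-ADE
    termination splitting), "sentence", or "paragraph" (used for the
    scope-resolution comparison).
    """
    if boundary_mode == "paragraph":
        return _paragraph_units(text, doc_id)
    if boundary_mode == "sentence":
        return _sentence_units(text, doc_id)
    if boundary_mode != "clause":
        raise ValueError(f"unknown boundary_mode {boundary_mode!r}")
    units: List[Clause] = []
    for sentence in split_sentences(text, doc_id):
        for clause in split_clauses(sentence, text):
            hits = ade_hits(clause, text, lexicon)
            if len(hits) >= 2:
                units.extend(split_multi_ade_clause(clause, hits, lexicon,
                                                    text))
            else:
                units.append(clause)
    return units


def annotate_document(text: str, doc_id: str = "doc",
                      lexicon: Optional[Lexicon] = None,
                      rules: Optional[RuleCatalogue] = None,
                      boundary_mode: str = "clause") -> List[Annotation]:
    """Run the full pipeline on one document; annotations ordered by
    offset.  Malformed text never raises; configuration errors propagate."""
    lexicon = lexicon or default_lexicon()
    rules = rules or default_rules()
    annotations: List[Annotation] = []
    for unit in segment(text, doc_id, lexicon, boundary_mode):
        mentions = detect_mentions([unit], text, lexicon)
        if not mentions:
            continue
        triggers = find_triggers(unit, text, lexicon)
        view = ClauseView(unit, text, lexicon)
        for mention in mentions:
            ctx = assign_context(mention, triggers)
            retention = apply_retention_rules(mention, ctx, view, rules)
            removal = apply_removal_rules(mention, ctx, view, rules)
            final_negation, rule_id = resolve(mention, retention, removal,
                                              ctx)
            categorical = ctx.categorical_value
            if rule_id is not None and removal.fired \
                    and rule_id == removal.rule_id \
                    and rule_category(rules, rule_id) == "b":
                # uncertainty removals record a general-discussion value
                categorical = CategoricalValue.GENERAL_DISCUSSION
            status = derive_status(ctx.experiencer, final_negation,
                                   ctx.temporality, categorical)
            if retention.fired:
                status = AdeStatus.POSITIVE
            annotations.append(Annotation(
                doc_id=doc_id, ade_type=mention.ade_concept,
                experiencer=ctx.experiencer, negation=final_negation,
                temporality=ctx.temporality, categorical_value=categorical,
                refinement_rule=rule_id, ade_status=status,
                clause=text[unit.start:unit.end],
                start=mention.start, end=mention.end))
    annotations.sort(key=lambda a: (a.start, a.end))
    return annotations


def annotate_corpus(docs: Sequence[dict],
                    lexicon: Optional[Lexicon] = None,
                    rules: Optional[RuleCatalogue] = None,
                    boundary_mode: str = "clause") -> List[Annotation]:
    """Annotate a corpus of {id, text} records."""
    out: List[Annotation] = []
    for doc in docs:
        out.extend(annotate_document(doc["text"], doc_id=doc["id"],
                                     lexicon=lexicon, rules=rules,
                                     boundary_mode=boundary_mode))
    return out


# -------------------------------------------------------------------- I/O
def write_annotations(annotations: Sequence[Annotation], path: Path,
                      fmt: str = "jsonl",
                      texts: Optional[Dict[str, str]] = None) -> None:
    """Write annotations as JSONL (one object per annotation) or BRAT
    standoff (.ann per document; requires `texts` for the .txt files)."""
    path = Path(path)
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for a in annotations:
                fh.write(json.dumps(a.to_dict(), sort_keys=True) + "\n")
        return
    if fmt != "brat":
        raise ValueError(f"unknown format {fmt!r}")
    if texts is None:
        raise ValueError("brat output requires the source texts")
    path.mkdir(parents=True, exist_ok=True)
    by_doc: Dict[str, List[Annotation]] = {}
    for a in annotations:
        by_doc.setdefault(a.doc_id, []).append(a)
    for doc_id, text in texts.items():
        (path / f"{doc_id}.txt").write_text(text, encoding="utf-8")
        lines: List[str] = []
        a_idx = 1
        for t_idx, a in enumerate(sorted(by_doc.get(doc_id, []),
                                         key=lambda x: x.start), start=1):
            surface = text[a.start:a.end]
            lines.append(f"T{t_idx}\t{_brat_type(a.ade_type)} "
                         f"{a.start} {a.end}\t{surface}")
            for name, value in [("Negation", a.negation.value),
                                ("Experiencer", a.experiencer.value),
                                ("Temporality", a.temporality.value),
                                ("Categorical_Value",
                                 a.categorical_value.value),
                                ("ADE_status", a.ade_status.value)]:
                lines.append(f"A{a_idx}\t{name} T{t_idx} {value}")
                a_idx += 1
        (path / f"{doc_id}.ann").write_text("\n".join(lines) + "\n"
                                            if lines else "",
                                            encoding="utf-8")


def _brat_type(concept: str) -> str:
    return concept.replace(" ", "_")


def read_annotations(path: Path) -> List[Annotation]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(Annotation.from_dict(json.loads(line)))
    return out


def write_gold(gold: Sequence[GoldAnnotation], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in gold:
            fh.write(json.dumps(g.to_dict(), sort_keys=True) + "\n")


def read_gold(path: Path) -> List[GoldAnnotation]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(GoldAnnotation.from_dict(json.loads(line)))
    return out
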