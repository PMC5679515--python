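"""Scoring predicted annotations against a gold standard.

Mentions are paired by (document, concept, overlapping span).  For a pair,
TP = both positive, TN = both negative, FP = predicted positive only,
FN = gold positive only.  A partial (non-identical) span overlap with
conflicting statuses resolves toward the negative cell (TN) by default.
Unpaired gold positives count FN, unpaired gold negatives TN, unpaired
predicted positives FP; unpaired predicted negatives are not scored.
Ratios with zero denominators are NaN, never 0.
"""
from __future__ import annotations

import math
from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd

from .types import (AdeStatus, Annotation, ConfusionCounts, GoldAnnotation,
                    MetricsReport, NAN)


class EvaluationError(Exception):
    pass


def _pair_key(doc_id: str, concept: str) -> tuple:
    return (doc_id, concept)


def match_and_count(gold: Sequence[GoldAnnotation],
                    pred: Sequence[Annotation],
                    per_ade: bool = False,
                    partial_conflict_to_negative: bool = True,
                    doc_ids: Optional[Iterable[str]] = None
                    ) -> Union[ConfusionCounts, Dict[str, ConfusionCounts]]:
    """Confusion counts from paired gold/predicted mentions.

    `doc_ids`, when given, is the universe of gold-corpus documents; a
    prediction for a document outside it is a validation error.
    """
    if doc_ids is not None:
        universe = set(doc_ids)
        unknown = {p.doc_id for p in pred} - universe
        if unknown:
            raise EvaluationError(
                f"predicted documents absent from gold corpus: "
                f"{sorted(unknown)[:5]}")
    by_key_gold: Dict[tuple, List[GoldAnnotation]] = defaultdict(list)
    by_key_pred: Dict[tuple, List[Annotation]] = defaultdict(list)
    for g in gold:
        by_key_gold[_pair_key(g.doc_id, g.ade_concept)].append(g)
    for p in pred:
        by_key_pred[_pair_key(p.doc_id, p.ade_type)].append(p)

    counts: Dict[str, ConfusionCounts] = defaultdict(ConfusionCounts)
    for key in set(by_key_gold) | set(by_key_pred):
        concept = key[1]
        golds = sorted(by_key_gold.get(key, []), key=lambda g: g.start)
        preds = sorted(by_key_pred.get(key, []), key=lambda p: p.start)
        used = [False] * len(preds)
        c = counts[concept]
        for g in golds:
            match_i = None
            for i, p in enumerate(preds):
                if used[i]:
                    continue
                if p.start < g.end and g.start < p.end:
                    match_i = i
                    break
            if match_i is None:
                if g.gold_status is AdeStatus.POSITIVE:
                    c.fn += 1
                else:
                    c.tn += 1
                continue
            used[match_i] = True
            p = preds[match_i]
            exact = (p.start, p.end) == (g.start, g.end)
            gp = g.gold_status is AdeStatus.POSITIVE
            pp = p.ade_status is AdeStatus.POSITIVE
            if not exact and gp != pp and partial_conflict_to_negative:
                c.tn += 1
            elif gp and pp:
                c.tp += 1
            elif gp and not pp:
                c.fn += 1
            elif pp:
                c.fp += 1
            else:
                c.tn += 1
        for i, p in enumerate(preds):
            if not used[i] and p.ade_status is AdeStatus.POSITIVE:
                c.fp += 1
    if per_ade:
        return dict(counts)
    total = ConfusionCounts()
    for c in counts.values():
        total = total + c
    return total


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else NAN


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Precision, sensitivity, specificity, accuracy and F-measure."""
    if c.total == 0:
        raise EvaluationError("empty evaluation set")
    precision = _ratio(c.tp, c.tp + c.fp)
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    accuracy = (c.tp + c.tn) / c.total
    if math.isnan(precision) or math.isnan(sensitivity) \
            or precision + sensitivity == 0:
        f = NAN
    else:
        f = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(precision=precision, sensitivity=sensitivity,
                         specificity=specificity, accuracy=accuracy,
                         f_measure=f)


def metrics_table(per_ade: Dict[str, ConfusionCounts],
                  ndigits: int = 2) -> pd.DataFrame:
    """Per-concept report table (rounded only here, at presentation)."""
    rows = []
    for concept in sorted(per_ade):
        c = per_ade[concept]
        m = compute_metrics(c)
        rows.append({
            "ADE": concept, "Total": c.total, "TP": c.tp, "TN": c.tn,
            "FP": c.fp, "FN": c.fn,
            "Precision": round(m.precision, ndigits),
            "Sensitivity": round(m.sensitivity, ndigits),
            "Specificity": round(m.specificity, ndigits),
            "Accuracy": round(m.accuracy, ndigits),
            "F-measure": round(m.f_measure, ndigits),
        })
    return pd.DataFrame(rows)
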