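"""Core domain types for the annotation pipeline.

Offsets are 0-based, half-open and document-absolute throughout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Category(str, Enum):
    ADE = "ade"
    DRUG = "drug"
    HELPING = "helping"
    CONTEXTUAL = "contextual"


class HelpingSub(str, Enum):
    OCCURRENCE = "occurrence"
    ADMINISTRATION = "administration"
    MONITORING = "monitoring"
    NEGATIVE_EFFECT = "negative_effect"
    DRUG_LINK = "drug_link"


class ContextualSub(str, Enum):
    EXPERIENCER = "experiencer"
    NEGATION = "negation"
    POSSIBILITY = "possibility"
    TERMINATION = "termination"
    TEMPORALITY_HYPOTHETICAL = "temporality_hypothetical"


class Direction(str, Enum):
    FORWARD = "forward"
    BACKWARD = "backward"
    BIDIRECTIONAL = "bidirectional"


class Dimension(str, Enum):
    """Which assignment dimension a temporality/hypothetical trigger drives."""

    TEMPORALITY = "temporality"
    HYPOTHETICAL = "hypothetical"


class Experiencer(str, Enum):
    PATIENT = "patient"
    OTHER = "other"


class NegationState(str, Enum):
    AFFIRMED = "affirmed"
    NEGATED = "negated"


class Temporality(str, Enum):
    RECENT = "recent"
    HISTORICAL = "historical"


class CategoricalValue(str, Enum):
    ASSERTIVE = "assertive"
    HYPOTHETICAL = "hypothetical"
    RETROSPECTIVE = "retrospective"
    GENERAL_DISCUSSION = "general_discussion"


class AdeStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class SplitOrigin(str, Enum):
    DELIMITER = "delimiter"
    TERMINATION_TERM = "termination_term"
    WHOLE_SENTENCE = "whole_sentence"


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary row: a literal surface form plus its concept label."""

    surface: str
    canonical: str
    category: Category
    subcategory: Optional[str] = None
    case_sensitive: bool = False
    direction: Direction = Direction.FORWARD
    dimension: Optional[Dimension] = None

    def __post_init__(self) -> None:
        norm = " ".join(self.surface.split())
        object.__setattr__(self, "surface", norm)
        if not norm:
            raise ValueError("empty surface")

    @property
    def key(self) -> tuple:
        return (self.surface.casefold(), self.category, self.subcategory)


@dataclass(frozen=True)
class TermHit:
    """A dictionary surface located in text."""

    entry: LexiconEntry
    start: int
    end: int


@dataclass(frozen=True)
class Sentence:
    doc_id: str
    start: int
    end: int


@dataclass(frozen=True)
class Clause:
    """Delimiter-bounded sub-sentence span: the unit of annotation scope."""

    doc_id: str
    sentence: Sentence
    start: int
    end: int
    split_origin: SplitOrigin = SplitOrigin.WHOLE_SENTENCE


@dataclass(frozen=True)
class Mention:
    doc_id: str
    clause: Clause
    ade_concept: str
    start: int
    end: int
    provisional_status: AdeStatus = AdeStatus.POSITIVE


@dataclass(frozen=True)
class TriggerHit:
    """A contextual trigger with the region of the clause it governs."""

    entry: LexiconEntry
    start: int
    end: int
    direction: Direction
    scope_start: int
    scope_end: int


@dataclass(frozen=True)
class ContextAssignment:
    experiencer: Experiencer = Experiencer.PATIENT
    negation: NegationState = NegationState.AFFIRMED
    temporality: Temporality = Temporality.RECENT
    categorical_value: CategoricalValue = CategoricalValue.ASSERTIVE
    triggers_fired: tuple = ()


class RefinementAction(str, Enum):
    RETAIN_POSITIVE = "retain_positive"
    MARK_NEGATIVE = "mark_negative"
    NONE = "none"


@dataclass(frozen=True)
class RefinementOutcome:
    rule_id: Optional[str] = None
    action: RefinementAction = RefinementAction.NONE
    evidence_span: Optional[tuple] = None

    def __post_init__(self) -> None:
        if (self.rule_id is None) != (self.action is RefinementAction.NONE):
            raise ValueError("rule_id must be set iff an action was taken")

    @property
    def fired(self) -> bool:
        return self.action is not RefinementAction.NONE


@dataclass(frozen=True)
class Annotation:
    """Final record: one ADE mention with its full feature set."""

    doc_id: str
    ade_type: str
    experiencer: Experiencer
    negation: NegationState
    temporality: Temporality
    categorical_value: CategoricalValue
    refinement_rule: Optional[str]
    ade_status: AdeStatus
    clause: str
    start: int
    end: int

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "ade_type": self.ade_type,
            "experiencer": self.experiencer.value,
            "negation": self.negation.value,
            "temporality": self.temporality.value,
            "categorical_value": self.categorical_value.value,
            "refinement_rule": self.refinement_rule,
            "ade_status": self.ade_status.value,
            "clause": self.clause,
            "start": self.start,
            "end": self.end,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Annotation":
        return cls(
            doc_id=d["doc_id"],
            ade_type=d["ade_type"],
            experiencer=Experiencer(d["experiencer"]),
            negation=NegationState(d["negation"]),
            temporality=Temporality(d["temporality"]),
            categorical_value=CategoricalValue(d["categorical_value"]),
            refinement_rule=d.get("refinement_rule"),
            ade_status=AdeStatus(d["ade_status"]),
            clause=d["clause"],
            start=d["start"],
            end=d["end"],
        )


@dataclass(frozen=True)
class GoldAnnotation:
    doc_id: str
    ade_concept: str
    start: int
    end: int
    gold_status: AdeStatus

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "ade_concept": self.ade_concept,
            "start": self.start,
            "end": self.end,
            "gold_status": self.gold_status.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GoldAnnotation":
        return cls(d["doc_id"], d["ade_concept"], d["start"], d["end"],
                   AdeStatus(d["gold_status"]))


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    """Precision, sensitivity (recall), specificity, accuracy and F-measure.

    Ratios with a zero denominator are reported as NaN, never as 0.
    """

    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    f_measure: float

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f_measure": self.f_measure,
        }


NAN = float("nan")


def is_defined(x: float) -> bool:
    return not math.isnan(x)
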