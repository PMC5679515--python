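"""Seeded generator of pseudo-clinical notes with gold annotations.

The generator emulates the contextual phenomena the pipeline targets in
short psychiatric progress notes — affirmed, negated, hypothetical,
historical, other-experiencer, warning/monitoring, questionnaire,
organisation-name/e-mail and uncertainty contexts, plus multi-ADE clauses
at a configurable rate (default 5% of mention-bearing clauses) — without
any patient data.  Patient names are masked as "ZZZZZ", mimicking
de-identified records.  Every inserted ADE surface is logged as a gold
annotation whose status is implied by its template category (affirmed and
negated-but-retained templates are positive; everything else negative).

The generator shares only the dictionary with the pipeline: it writes
sentences from its own templates and never calls the annotation code.
"""
from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .lexicon import Lexicon, default_lexicon
from .types import AdeStatus, GoldAnnotation

DEFAULT_ADE_CONCEPTS = [
    "agitation", "akathisia", "arrhythmia", "cardiomyopathy",
    "constipation", "convulsions", "diarrhoea", "dizziness", "dry mouth",
    "galactorrhoea", "hypersalivation", "insomnia", "myocarditis", "nausea",
    "pneumonia", "sedation", "sjs", "tachycardia", "weight gain",
]

DEFAULT_CONTEXT_MIX = {
    "affirmed": 0.30,
    "negated": 0.25,
    "hypothetical": 0.08,
    "historical": 0.08,
    "other_experiencer": 0.07,
    "warning_monitoring": 0.10,
    "questionnaire": 0.05,
    "org_name_email": 0.02,
    "uncertainty": 0.05,
}

_DRUGS = ["olanzapine", "clozapine", "risperidone", "quetiapine",
          "sertraline", "fluoxetine", "citalopram", "mirtazapine",
          "lithium", "aripiprazole"]

_FILLERS = [
    "ZZZZZ attended the ward round today.",
    "Slept well overnight.",
    "Seen by the occupational therapist this morning.",
    "Plans for weekend leave were agreed.",
    "Engaged well in the group session.",
    "Appetite remains good.",
    "Spent the afternoon in the communal area.",
    "Family visited during the evening.",
]


class GenerationError(Exception):
    pass


@dataclass
class GenerationConfig:
    n_docs: int = 100
    seed: int = 0
    ade_concepts: Optional[List[str]] = None
    context_mix: Optional[Dict[str, float]] = None
    multi_ade_clause_rate: float = 0.05
    typo_rate: float = 0.0
    filler_rate: float = 0.3
    include_canonical: bool = True

    def __post_init__(self) -> None:
        mix = self.context_mix or DEFAULT_CONTEXT_MIX
        unknown = set(mix) - set(DEFAULT_CONTEXT_MIX)
        if unknown:
            raise GenerationError(f"unknown context categories: {unknown}")
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise GenerationError(f"context_mix must sum to 1, got {total}")
        if not 0.0 <= self.multi_ade_clause_rate <= 1.0:
            raise GenerationError("multi_ade_clause_rate must be in [0,1]")
        self.context_mix = dict(mix)
        self.ade_concepts = list(self.ade_concepts or DEFAULT_ADE_CONCEPTS)


# ------------------------------------------------------------- templates
# Each template maps a surface (and sometimes a drug) into a sentence and
# yields (sentence, [(relative_offset, surface, status), ...]).
_POS = AdeStatus.POSITIVE
_NEG = AdeStatus.NEGATIVE


def _fill(template: str, surface: str, drug: str = "",
          status: AdeStatus = _POS, upper: bool = False
          ) -> Tuple[str, List[Tuple[int, str, AdeStatus]]]:
    s = surface.upper() if upper else surface
    text = template.format(S=s, D=drug)
    if template.startswith("{S}"):
        text = text[0].upper() + text[1:]
        s = text[:len(s)]
    off = text.upper().find(s.upper())
    assert off >= 0
    return text, [(off, s, status)]


_TEMPLATES: Dict[str, List] = {
    "affirmed": [
        lambda s, d: _fill("The patient is still suffering from a light "
                           "{S}.", s, status=_POS),
        lambda s, d: _fill("ZZZZZ continues to complain of {S}.", s,
                           status=_POS),
        lambda s, d: _fill("He reports {S} since starting {D}.", s, d,
                           status=_POS),
        lambda s, d: _fill("She is experiencing {S} on the current dose.",
                           s, status=_POS),
        lambda s, d: _fill("ZZZZZ developed {S} after the dose increase.",
                           s, status=_POS),
        lambda s, d: _fill("Still troubled by {S} this week.", s,
                           status=_POS),
        # retention situations: negation vocabulary present, event real
        lambda s, d: _fill("ZZZZZ appeared to be {S} and not taking his "
                           "medication.", s, status=_POS),
        lambda s, d: _fill("His {S} has not worsened on the increased dose "
                           "of beta-blocker.", s, status=_POS),
        lambda s, d: _fill("ZZZZZ reports no relief from {S}.", s,
                           status=_POS),
    ],
    "negated": [
        lambda s, d: _fill("No complaints of {S}.", s, status=_NEG),
        lambda s, d: _fill("He did not complain of {S}.", s, status=_NEG),
        lambda s, d: _fill("ZZZZZ denies {S}.", s, status=_NEG),
        lambda s, d: _fill("There was no {S} today.", s, status=_NEG),
        lambda s, d: _fill("She has not experienced {S}.", s, status=_NEG),
    ],
    "hypothetical": [
        lambda s, d: _fill("If {S} develops, contact the team.", s,
                           status=_NEG),
        lambda s, d: _fill("Should {S} occur, stop taking the tablets.", s,
                           status=_NEG),
    ],
    "historical": [
        lambda s, d: _fill("She previously experienced {S}.", s,
                           status=_NEG),
        lambda s, d: _fill("History of {S} as a child.", s, status=_NEG),
        lambda s, d: _fill("ZZZZZ had {S} in the past.", s, status=_NEG),
    ],
    "other_experiencer": [
        lambda s, d: _fill("His mother had {S}.", s, status=_NEG),
        lambda s, d: _fill("Her father suffers from {S}.", s, status=_NEG),
        lambda s, d: _fill("Her sister reported {S}.", s, status=_NEG),
    ],
    "warning_monitoring": [
        lambda s, d: _fill("I am changing the dose and have warned ZZZZZ "
                           "of {S}.", s, status=_NEG),
        lambda s, d: _fill("Signs of {S}, ongoing investigation.", s,
                           status=_NEG),
        lambda s, d: _fill("The patient is starting {D}, explained her as "
                           "it can cause {S}.", s, d, status=_NEG),
        lambda s, d: _fill("Monitor for {S} at the next review.", s,
                           status=_NEG),
        lambda s, d: _fill("Advised about the risk of {S} with {D}.", s, d,
                           status=_NEG),
    ],
    "questionnaire": [
        lambda s, d: _fill("{S} *No * Yes.", s, status=_NEG),
        lambda s, d: _fill("Do you feel {S}: Yes/No.", s, status=_NEG),
        lambda s, d: _fill("{S} score x 3.", s, status=_NEG),
    ],
    "org_name_email": [
        lambda s, d: _fill("Referred to the CENTRE FOR {S} DISORDERS AND "
                           "TRAUMA.", s, status=_NEG, upper=True),
        lambda s, d: _fill("Contact {S}@sydenham.lewisham.sch.uk for an "
                           "appointment.", s, status=_NEG),
        lambda s, d: _fill("See www.nhs.uk/Conditions/{S} for "
                           "information.", s, status=_NEG),
    ],
    "uncertainty": [
        lambda s, d: _fill("Query {S} today.", s, status=_NEG),
        lambda s, d: _fill("Unclear whether {S} is present.", s,
                           status=_NEG),
        lambda s, d: _fill("?{S} on examination.", s, status=_NEG),
    ],
}

# org templates 1 and 2 embed the surface in an e-mail/URL token: they need
# a single-token surface
_SINGLE_TOKEN_ONLY = {"org_name_email": (1, 2)}


def _multi_template(s1: str, s2: str, rng: random.Random
                    ) -> Tuple[str, List[Tuple[int, str, AdeStatus]]]:
    if rng.random() < 0.5:
        text = (f"The patient is still complaining of {s1} but not {s2}.")
        g1 = (text.find(s1), s1, _POS)
        g2 = (text.rfind(s2), s2, _NEG)
    else:
        text = f"No {s1} however she reports {s2}."
        g1 = (text.find(s1), s1, _NEG)
        g2 = (text.rfind(s2), s2, _POS)
    return text, [g1, g2]


# ------------------------------------------------------- canonical fixtures
# Worked examples of the phenomena the pipeline targets, always emitted
# first when include_canonical and n_docs >= 19 so regression tests can pin
# them.  Each: (text, [(surface_as_written, occurrence_index, concept,
# status), ...]).
CANONICAL_DOCS: List[Tuple[str, List[Tuple[str, int, str, AdeStatus]]]] = [
    ("Late shift ZZZZZ has wandered in and out of her room throughout the "
     "afternoon. No complaints of dizziness.",
     [("dizziness", 0, "dizziness", _NEG)]),
    ("He did not complain of constipation. The patient is still suffering "
     "from a light headache.",
     [("constipation", 0, "constipation", _NEG),
      ("headache", 0, "headache", _POS)]),
    ("The patient is still complaining of headache but not constipation.",
     [("headache", 0, "headache", _POS),
      ("constipation", 0, "constipation", _NEG)]),
    ("ZZZZZ appeared to be disorientated and not taking his medication.",
     [("disorientated", 0, "disorientation", _POS)]),
    ("ZZZZZ restlessness has not worsened on the increased dose of "
     "beta-blocker.",
     [("restlessness", 0, "restlessness", _POS)]),
    ("I am changing the dose and have warned ZZZZ of dizziness.",
     [("dizziness", 0, "dizziness", _NEG)]),
    ("Signs of myocarditis, on going investigation.",
     [("myocarditis", 0, "myocarditis", _NEG)]),
    ("The patient is starting Olanzapine, explained her as it can cause "
     "weight gain.",
     [("weight gain", 0, "weight gain", _NEG)]),
    ("She has had 4 seizures within the last 2 weeks, unstable partial "
     "complex seizures.",
     [("seizures", 0, "seizures", _POS),
      ("seizures", 1, "seizures", _NEG)]),
    ("Fainting/ dizziness *No * Yes.",
     [("Fainting", 0, "fainting", _NEG),
      ("dizziness", 0, "dizziness", _NEG)]),
    ("I become irritable, restless and nervous x 5.",
     [("restless", 0, "restlessness", _NEG)]),
    ("Referred to the CENTRE FOR ANXIETY DISORDERS AND TRAUMA.",
     [("ANXIETY", 0, "anxiety", _NEG)]),
    ("Contact sjs@sydenham.lewisham.sch.uk for an appointment.",
     [("sjs", 0, "sjs", _NEG)]),
    ("See www.nhs.uk/Conditions/Anxiety for information.",
     [("Anxiety", 0, "anxiety", _NEG)]),
]


def _canonical(doc_id: str) -> Tuple[dict, List[GoldAnnotation]]:
    idx = int(doc_id.rsplit("-", 1)[1])
    text, specs = CANONICAL_DOCS[idx]
    gold = []
    for surface, occurrence, concept, status in specs:
        start = -1
        for _ in range(occurrence + 1):
            start = text.find(surface, start + 1)
        assert start >= 0
        gold.append(GoldAnnotation(doc_id, concept, start,
                                   start + len(surface), status))
    return {"id": doc_id, "text": text}, gold


# ------------------------------------------------------------- generation
def _surface_for(lexicon: Lexicon, concept: str, rng: random.Random,
                 single_token: bool = False) -> Optional[str]:
    surfaces = lexicon.surfaces_for_concept(concept)
    if single_token:
        surfaces = [s for s in surfaces
                    if re.fullmatch(r"[A-Za-z]+", s)]
    return rng.choice(surfaces) if surfaces else None


def _protected_tokens(lexicon: Lexicon) -> frozenset:
    toks = {"yes", "no", "x", "zzzzz", "zzzz"}
    for e in lexicon.entries:
        toks.update(t.casefold() for t in e.surface.split())
    return frozenset(toks)


def _inject_typos(text: str, gold: Sequence[GoldAnnotation],
                  protected: frozenset, rate: float,
                  rng: random.Random) -> str:
    """Swap two interior characters of eligible tokens; never touches gold
    spans, dictionary vocabulary or non-alphabetic tokens, and preserves
    length so offsets stay valid."""
    if rate <= 0:
        return text
    spans = [(g.start, g.end) for g in gold]
    chars = list(text)
    for m in re.finditer(r"[A-Za-z]{4,}", text):
        if m.group(0).casefold() in protected:
            continue
        if any(m.start() < e and s < m.end() for s, e in spans):
            continue
        if rng.random() < rate:
            i = rng.randrange(m.start() + 1, m.end() - 2)
            chars[i], chars[i + 1] = chars[i + 1], chars[i]
    return "".join(chars)


def generate_corpus(config: GenerationConfig,
                    lexicon: Optional[Lexicon] = None
                    ) -> Tuple[List[dict], List[GoldAnnotation]]:
    """Generate (documents, gold).  Identical config+seed gives a
    byte-identical corpus."""
    lexicon = lexicon or default_lexicon()
    known = set(lexicon.concepts())
    unknown = set(config.ade_concepts) - known
    if unknown:
        raise GenerationError(f"unknown ade_concept(s): {sorted(unknown)}")
    rng = random.Random(config.seed)
    protected = _protected_tokens(lexicon)
    categories = sorted(config.context_mix)
    weights = [config.context_mix[c] for c in categories]

    docs: List[dict] = []
    gold: List[GoldAnnotation] = []
    n_canonical = (len(CANONICAL_DOCS)
                   if config.include_canonical
                   and config.n_docs >= len(CANONICAL_DOCS) else 0)
    for i in range(n_canonical):
        doc, g = _canonical(f"canon-{i}")
        docs.append(doc)
        gold.extend(g)

    for i in range(config.n_docs - n_canonical):
        doc_id = f"synth-{i:04d}"
        n_sent = rng.randint(1, 30)
        sentences: List[Tuple[str, List[Tuple[int, str, AdeStatus, str]]]] \
            = []
        for _ in range(n_sent):
            if rng.random() < config.filler_rate:
                sentences.append((rng.choice(_FILLERS), []))
                continue
            if rng.random() < config.multi_ade_clause_rate:
                c1, c2 = rng.sample(config.ade_concepts, 2)
                s1 = _surface_for(lexicon, c1, rng)
                s2 = _surface_for(lexicon, c2, rng)
                text, items = _multi_template(s1, s2, rng)
                concept_by_surface = {s1: c1, s2: c2}
                sentences.append((text, [(o, s, st, concept_by_surface[s])
                                         for o, s, st in items]))
                continue
            category = rng.choices(categories, weights=weights, k=1)[0]
            t_idx = rng.randrange(len(_TEMPLATES[category]))
            concept = rng.choice(config.ade_concepts)
            single = t_idx in _SINGLE_TOKEN_ONLY.get(category, ())
            surface = _surface_for(lexicon, concept, rng,
                                   single_token=single)
            if surface is None:
                surface = _surface_for(lexicon, concept, rng)
                t_idx = 0  # fall back to the first template
            drug = rng.choice(_DRUGS)
            text, items = _TEMPLATES[category][t_idx](surface, drug)
            sentences.append((text, [(o, s, st, concept)
                                     for o, s, st in items]))
        # assemble into paragraphs of 1-4 sentences
        parts: List[str] = []
        pos = 0
        doc_gold: List[GoldAnnotation] = []
        remaining = sentences[:]
        while remaining:
            k = min(len(remaining), rng.randint(1, 4))
            para, remaining = remaining[:k], remaining[k:]
            for j, (stext, items) in enumerate(para):
                for off, surf, status, concept in items:
                    doc_gold.append(GoldAnnotation(
                        doc_id, concept, pos + off, pos + off + len(surf),
                        status))
                parts.append(stext)
                pos += len(stext)
                if j < len(para) - 1:
                    parts.append(" ")
                    pos += 1
            if remaining:
                parts.append("\n\n")
                pos += 2
        text = "".join(parts)
        text = _inject_typos(text, doc_gold, protected, config.typo_rate,
                             rng)
        docs.append({"id": doc_id, "text": text})
        gold.extend(doc_gold)
    return docs, gold


def write_corpus(docs: Sequence[dict], gold: Sequence[GoldAnnotation],
                 out_dir: Path) -> None:
    """Write one .txt per document plus a JSONL gold file."""
    from .pipeline import write_gold
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (out_dir / f"{doc['id']}.txt").write_text(doc["text"],
                                                  encoding="utf-8")
    write_gold(gold, out_dir / "gold.jsonl")
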