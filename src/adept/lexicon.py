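"""Dictionary loading, validation and longest-match term scanning.

The pipeline is driven by four dictionary categories: ADE terms (the events
to annotate, each mapped to a canonical concept), drug terms, helping terms
(occurrence / administration / monitoring / negative-effect / drug-link
vocabulary used by the refinement rules) and contextual trigger terms (the
five ConText-style subcategories of Table-2 shape: experiencer, negation,
possibility, termination, temporality & hypothetical).

Matching semantics: case-insensitive (unless an entry is flagged
case-sensitive), at token boundaries, leftmost-longest, non-overlapping;
internal whitespace in multi-word surfaces matches any single run of
whitespace.
"""
from __future__ import annotations

import csv
import logging
import re
from collections import defaultdict
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .types import (Category, ContextualSub, Dimension, Direction,
                    HelpingSub, LexiconEntry, TermHit)

logger = logging.getLogger(__name__)

_VALID_SUBCATEGORIES = {
    Category.ADE: set(),
    Category.DRUG: set(),
    Category.HELPING: {s.value for s in HelpingSub},
    Category.CONTEXTUAL: {s.value for s in ContextualSub},
}


class LexiconError(Exception):
    """Base class for dictionary problems."""


class LexiconConfigError(LexiconError):
    """A dictionary file is missing or the configuration is incomplete."""


class LexiconValidationError(LexiconError):
    """A dictionary row is malformed; the message carries the line number."""


class Lexicon:
    """An indexed, validated set of dictionary entries."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        collapsed: Dict[tuple, LexiconEntry] = {}
        for e in entries:
            if e.key in collapsed:
                logger.warning("duplicate lexicon entry collapsed: %r "
                               "(%s/%s)", e.surface, e.category.value,
                               e.subcategory)
                continue
            collapsed[e.key] = e
        self.entries: List[LexiconEntry] = list(collapsed.values())
        self._by_group: Dict[tuple, List[LexiconEntry]] = defaultdict(list)
        for e in self.entries:
            self._by_group[(e.category, None)].append(e)
            if e.subcategory is not None:
                self._by_group[(e.category, e.subcategory)].append(e)
        self._scanners: Dict[tuple, "_Scanner"] = {}

    # -- introspection -----------------------------------------------------
    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = defaultdict(int)
        for e in self.entries:
            out[e.category.value] += 1
        return dict(out)

    def subcategory_counts(self, category: Category) -> Dict[str, int]:
        out: Dict[str, int] = defaultdict(int)
        for e in self.entries:
            if e.category is category:
                out[e.subcategory or ""] += 1
        return dict(out)

    def entries_for(self, category: Category,
                    subcategory: Optional[str] = None) -> List[LexiconEntry]:
        return list(self._by_group.get((category, subcategory), []))

    def concepts(self, category: Category = Category.ADE) -> List[str]:
        seen: Dict[str, None] = {}
        for e in self.entries:
            if e.category is category:
                seen.setdefault(e.canonical, None)
        return list(seen)

    def surfaces_for_concept(self, concept: str) -> List[str]:
        return [e.surface for e in self.entries
                if e.category is Category.ADE and e.canonical == concept]

    # -- scanning ----------------------------------------------------------
    def scanner(self, category: Category,
                subcategory: Optional[str] = None) -> "_Scanner":
        key = (category, subcategory)
        if key not in self._scanners:
            self._scanners[key] = _Scanner(self.entries_for(category,
                                                            subcategory))
        return self._scanners[key]


class _Scanner:
    """Compiled leftmost-longest gazetteer scanner for one entry group."""

    def __init__(self, entries: Sequence[LexiconEntry]):
        self._ci: Dict[str, LexiconEntry] = {}
        self._cs: Dict[str, LexiconEntry] = {}
        for e in entries:
            if e.case_sensitive:
                self._cs[e.surface] = e
            else:
                self._ci[e.surface.casefold()] = e
        self._re_ci = self._compile(self._ci.keys(), re.IGNORECASE)
        self._re_cs = self._compile(self._cs.keys(), 0)

    @staticmethod
    def _compile(surfaces: Iterable[str], flags: int):
        alts = sorted(surfaces, key=len, reverse=True)
        if not alts:
            return None
        parts = [r"\s+".join(re.escape(t) for t in s.split()) for s in alts]
        # lookahead capture yields candidates at every start position
        pat = r"(?=((?<!\w)(?:%s)(?!\w)))" % "|".join(parts)
        return re.compile(pat, flags)

    def _candidates(self, text: str) -> List[Tuple[int, int, LexiconEntry]]:
        cands: List[Tuple[int, int, LexiconEntry]] = []
        if self._re_ci is not None:
            for m in self._re_ci.finditer(text):
                s = m.group(1)
                entry = self._ci[" ".join(s.split()).casefold()]
                cands.append((m.start(1), m.end(1), entry))
        if self._re_cs is not None:
            for m in self._re_cs.finditer(text):
                s = m.group(1)
                entry = self._cs.get(" ".join(s.split()))
                if entry is not None:
                    cands.append((m.start(1), m.end(1), entry))
        return cands

    def scan(self, text: str) -> List[TermHit]:
        """Leftmost-longest, non-overlapping hits, sorted by start."""
        cands = sorted(self._candidates(text),
                       key=lambda c: (c[0], -(c[1] - c[0])))
        hits: List[TermHit] = []
        last_end = -1
        for start, end, entry in cands:
            if start >= last_end:
                hits.append(TermHit(entry=entry, start=start, end=end))
                last_end = end
        return hits


def match_terms(text: str, lexicon: Lexicon, category: Category,
                subcategory: Optional[str] = None,
                offset: int = 0) -> List[TermHit]:
    """Locate dictionary surfaces of one category inside a clause text.

    `offset` shifts the reported spans (use the clause's document-absolute
    start so downstream offsets stay document-absolute).
    """
    if not text:
        return []
    hits = lexicon.scanner(category, subcategory).scan(text)
    if offset:
        hits = [TermHit(h.entry, h.start + offset, h.end + offset)
                for h in hits]
    return hits


# ---------------------------------------------------------------- file I/O
_COLUMNS = ["surface", "canonical", "subcategory", "direction", "dimension",
            "case_sensitive"]


def _read_rows(path: Path) -> List[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample else ","
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or "surface" not in reader.fieldnames:
            raise LexiconValidationError(
                f"{path}: missing header with a 'surface' column")
        return list(reader)


def load_lexicon(paths: Mapping[str, Path]) -> Lexicon:
    """Load and validate the four dictionary files.

    `paths` maps category name ('ade', 'drug', 'helping', 'contextual') to a
    TSV/CSV file with header columns surface / canonical / subcategory
    (subcategory optional for ade and drug files; optional extra columns
    direction, dimension, case_sensitive).
    """
    entries: List[LexiconEntry] = []
    for cat_name, path in paths.items():
        try:
            category = Category(cat_name)
        except ValueError:
            raise LexiconConfigError(f"unknown lexicon category {cat_name!r}")
        path = Path(path)
        if not path.exists():
            raise LexiconConfigError(
                f"lexicon file for category {category.value!r} not found: "
                f"{path}")
        rows = _read_rows(path)
        n_before = len(entries)
        for lineno, row in enumerate(rows, start=2):
            surface = " ".join((row.get("surface") or "").split())
            if not surface:
                raise LexiconValidationError(
                    f"{path}:{lineno}: empty surface")
            sub = (row.get("subcategory") or "").strip() or None
            valid = _VALID_SUBCATEGORIES[category]
            if category in (Category.HELPING, Category.CONTEXTUAL):
                if sub not in valid:
                    raise LexiconValidationError(
                        f"{path}:{lineno}: unknown subcategory {sub!r} for "
                        f"category {category.value!r}")
            elif sub is not None:
                raise LexiconValidationError(
                    f"{path}:{lineno}: subcategory not allowed for "
                    f"category {category.value!r}")
            canonical = " ".join((row.get("canonical") or "").split()) \
                or surface.casefold()
            direction = Direction((row.get("direction") or "").strip()
                                  or "forward")
            dim_raw = (row.get("dimension") or "").strip()
            dimension = Dimension(dim_raw) if dim_raw else None
            cs = (row.get("case_sensitive") or "").strip().lower() in (
                "true", "1", "yes")
            entries.append(LexiconEntry(
                surface=surface, canonical=canonical, category=category,
                subcategory=sub, case_sensitive=cs, direction=direction,
                dimension=dimension))
        if len(entries) == n_before:
            raise LexiconValidationError(
                f"no entries for category {category.value}")
    return Lexicon(entries)


def write_lexicon(lexicon: Lexicon, paths: Mapping[str, Path]) -> None:
    """Write the lexicon back out, one file per category (round-trips
    load_lexicon)."""
    for cat_name, path in paths.items():
        category = Category(cat_name)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(_COLUMNS)
            for e in lexicon.entries:
                if e.category is not category:
                    continue
                w.writerow([e.surface, e.canonical, e.subcategory or "",
                            e.direction.value if e.category is
                            Category.CONTEXTUAL else "",
                            e.dimension.value if e.dimension else "",
                            "true" if e.case_sensitive else ""])


def bundled_lexicon_paths() -> Dict[str, Path]:
    base = resources.files("adept") / "data"
    return {cat: Path(str(base / f"{cat}.tsv"))
            for cat in ("ade", "drug", "helping", "contextual")}


@lru_cache(maxsize=1)
def default_lexicon() -> Lexicon:
    """The dictionary bundled with the package."""
    return load_lexicon(bundled_lexicon_paths())
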