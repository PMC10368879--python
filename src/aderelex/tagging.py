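"""Dictionary-based drug/ADE tagging and rule-based date tagging.

Matching is exact (no stemming, no fuzzy matching), case-insensitive, at
word boundaries, longest-match-wins.  The date tagger emits a generic
``DATE`` label: deciding whether a date belongs to a drug or an ADE needs
relational context that a span tagger does not have, so that distinction is
left to the annotator (or, in synthetic corpora, the generator).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .types import Entity, Sentence

__all__ = [
    "Lexicon",
    "load_lexicon",
    "default_lexicon",
    "tag_lexicon",
    "tag_dates",
    "tag_document",
]

LEXICON_CATEGORIES = ("DRUG", "ADE", "CAUSAL_TERM")
_CATEGORY_FILES = {"DRUG": "drugs.tsv", "ADE": "ades.tsv", "CAUSAL_TERM": "causal.tsv"}


@dataclass
class Lexicon:
    """Canonical term -> surface-variant sets for one category."""

    category: str
    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in LEXICON_CATEGORIES:
            raise ValueError(f"unknown lexicon category {self.category!r}")
        seen: dict[str, str] = {}
        for canonical, variants in self.entries.items():
            if not variants:
                raise ValueError(f"{canonical!r}: empty variant set")
            for v in variants:
                key = v.casefold()
                if key in seen and seen[key] != canonical:
                    raise ValueError(
                        f"variant {v!r} appears under both {seen[key]!r} "
                        f"and {canonical!r}"
                    )
                seen[key] = canonical

    def all_variants(self) -> list[str]:
        return sorted({v for vs in self.entries.values() for v in vs})

    def canonical_of(self, surface: str) -> str | None:
        key = surface.casefold()
        for canonical, variants in self.entries.items():
            if key in {v.casefold() for v in variants}:
                return canonical
        return None


def load_lexicon(path: str | Path, category: str) -> Lexicon:
    """Read a lexicon file with lines ``canonical<TAB>variant1|variant2|...``."""
    entries: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            canonical, variants = line.split("\t", 1)
        except ValueError:
            raise ValueError(f"{path} line {lineno}: expected TAB-separated fields") from None
        entries[canonical.strip()] = {v.strip() for v in variants.split("|") if v.strip()}
    return Lexicon(category=category, entries=entries)


def default_lexicon(category: str) -> Lexicon:
    """Packaged default lexicon (generic + brand drug names, ADE groups, cues)."""
    fname = _CATEGORY_FILES[category]
    ref = resources.files("aderelex") / "data" / "lexicons" / fname
    with resources.as_file(ref) as path:
        return load_lexicon(path, category)


def _variant_pattern(variants: list[str]) -> re.Pattern:
    # longest alternative first => leftmost-longest matching with finditer
    ordered = sorted(variants, key=len, reverse=True)
    alts = "|".join(re.escape(v).replace(r"\ ", r"\s+") for v in ordered)
    return re.compile(
        r"(?<![A-Za-z0-9])(?:" + alts + r")(?![A-Za-z0-9])", re.IGNORECASE
    )


def tag_lexicon(
    sentences: list[Sentence],
    lexicon: Lexicon,
    start_id: int = 1,
) -> list[Entity]:
    """Tag every lexicon variant occurring in ``sentences``.

    Offsets are document-level.  Within a category, overlapping shorter
    matches are suppressed (longest match wins; ties broken leftmost).
    Entity ids are ``T<start_id>``, ``T<start_id+1>``, ... in offset order.
    """
    if not lexicon.entries:
        return []
    pattern = _variant_pattern(lexicon.all_variants())
    out: list[Entity] = []
    n = start_id
    for sent in sentences:
        for m in pattern.finditer(sent.text):
            out.append(
                Entity(
                    entity_id=f"T{n}",
                    label=lexicon.category,
                    start=sent.start + m.start(),
                    end=sent.start + m.end(),
                    surface=m.group(0),
                )
            )
            n += 1
    return out


_MONTHS = (
    "January|February|March|April|May|June|July|August|September|October|"
    "November|December|Jan|Feb|Mar|Apr|Jun|Jul|Aug|Sep|Sept|Oct|Nov|Dec"
)

# a trailing "." is fine (sentence end) unless a digit follows (decimal/version)
_NUM_GUARD_L = r"(?<![\d./-])(?<!\d\.)"
_NUM_GUARD_R = r"(?![\d/-])(?!\.\d)"

_DATE_PATTERNS = [
    # ISO: 2017-03-14
    re.compile(_NUM_GUARD_L + r"\d{4}-\d{2}-\d{2}" + _NUM_GUARD_R),
    # 3/14/2017, 03/14/17
    re.compile(_NUM_GUARD_L + r"\d{1,2}/\d{1,2}/\d{2,4}" + _NUM_GUARD_R),
    # 3-14-2017, 3-14-17
    re.compile(_NUM_GUARD_L + r"\d{1,2}-\d{1,2}-\d{2,4}" + _NUM_GUARD_R),
    # January 5, 2017 | Jan. 5 2017 | Jan 2017
    re.compile(
        r"\b(?:" + _MONTHS + r")\.?\s+\d{1,2},?\s+\d{4}\b"
        r"|\b(?:" + _MONTHS + r")\.?\s+\d{4}\b",
        re.IGNORECASE,
    ),
]


def tag_dates(sentences: list[Sentence], start_id: int = 1) -> list[Entity]:
    """Tag calendar dates with the generic ``DATE`` label.

    Handles numeric forms (M/D/YYYY, M-D-YY, YYYY-MM-DD) and month-name
    forms ("January 5, 2017", "Jan 2017").  Dotted numbers like "2.3.1"
    are never matched.
    """
    out: list[Entity] = []
    n = start_id
    for sent in sentences:
        spans: list[tuple[int, int]] = []
        for pat in _DATE_PATTERNS:
            for m in pat.finditer(sent.text):
                if any(s < m.end() and m.start() < e for s, e in spans):
                    continue  # earlier (higher-priority) pattern already covers this
                spans.append((m.start(), m.end()))
        for s, e in sorted(spans):
            out.append(
                Entity(
                    entity_id=f"T{n}",
                    label="DATE",
                    start=sent.start + s,
                    end=sent.start + e,
                    surface=sent.text[s:e],
                )
            )
            n += 1
    return out


def tag_document(
    sentences: list[Sentence],
    lexicons: list[Lexicon],
    with_dates: bool = True,
) -> list[Entity]:
    """Run all taggers over one document's sentences with shared id numbering."""
    entities: list[Entity] = []
    next_id = 1
    for lex in lexicons:
        tags = tag_lexicon(sentences, lex, start_id=next_id)
        entities.extend(tags)
        next_id += len(tags)
    if with_dates:
        entities.extend(tag_dates(sentences, start_id=next_id))
    return sorted(entities, key=lambda e: (e.start, e.end))
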