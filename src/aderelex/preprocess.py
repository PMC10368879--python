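"""Text cleaning and rule-based sentence segmentation.

Cleaning runs BEFORE tagging/annotation in the pipeline, so no gold-offset
remapping across cleaning is ever required: annotations are always created
on already-cleaned text.

Segmentation follows a three-phase protect/split/restore scheme: substrings
that contain sentence-final-looking punctuation but are not boundaries
(known abbreviations, decimal numbers, numbered-list markers) are masked
with a placeholder character drawn from the Unicode private use area,
boundaries are found on the masked copy, and spans are mapped back onto the
untouched original string.  A lone newline is NOT a sentence boundary
(clinical notes wrap lines); a blank line IS.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .types import Sentence

__all__ = [
    "CleaningConfig",
    "clean_text",
    "segment_sentences",
    "DEFAULT_PROTECTED_ABBREVIATIONS",
    "PlaceholderCollisionError",
]

#: Shipped default list of period-bearing abbreviations that must not end a
#: sentence.  Illustrative, user-extendable; not a reconstruction of any
#: particular clinical system's list.
DEFAULT_PROTECTED_ABBREVIATIONS = [
    "Dr.", "Mr.", "Mrs.", "Ms.", "St.",
    "q.d.", "b.i.d.", "t.i.d.", "q.i.d.", "p.r.n.", "p.o.", "i.v.",
    "e.g.", "i.e.", "etc.", "vs.", "approx.", "No.",
    "a.m.", "p.m.",
]

_PLACEHOLDER = "\ue000"  # private use area; never occurs in printable notes


class PlaceholderCollisionError(RuntimeError):
    """Input text already contains the internal placeholder character."""


@dataclass
class CleaningConfig:
    """Knobs for :func:`clean_text`.

    ``variant_map`` maps surface variants (e.g. brand names) to canonical
    terms; ``abbreviation_map`` maps shorthand to expansions.  Both are
    applied case-insensitively at word boundaries, longest key first.
    """

    variant_map: dict[str, str] = field(default_factory=dict)
    abbreviation_map: dict[str, str] = field(default_factory=dict)
    collapse_whitespace: bool = True

    def __post_init__(self) -> None:
        for m in (self.variant_map, self.abbreviation_map):
            if any(not k for k in m):
                raise ValueError("replacement maps must not contain empty keys")


def _apply_map(text: str, mapping: dict[str, str]) -> str:
    if not mapping:
        return text
    folded = {k.lower(): v for k, v in mapping.items()}
    keys = sorted(folded, key=len, reverse=True)
    pattern = re.compile(
        r"(?<![A-Za-z0-9])(" + "|".join(re.escape(k) for k in keys) + r")(?![A-Za-z0-9])",
        re.IGNORECASE,
    )
    return pattern.sub(lambda m: folded[m.group(1).lower()], text)


def clean_text(raw: str, config: CleaningConfig | None = None) -> str:
    """Normalize whitespace and apply variant/abbreviation replacement.

    Runs of spaces and tabs collapse to one space; three or more consecutive
    newlines collapse to two (one blank line).  Idempotent as long as no
    replacement value is itself a key of either map.
    """
    if config is None:
        config = CleaningConfig()
    text = raw
    if config.collapse_whitespace:
        text = re.sub(r"[ \t]+", " ", text)
        text = re.sub(r" ?\n ?", "\n", text)
        text = re.sub(r"\n{3,}", "\n\n", text)
    text = _apply_map(text, config.variant_map)
    text = _apply_map(text, config.abbreviation_map)
    return text


_DEFAULT_NUMERIC_PATTERNS = [
    r"\d+\.\d+(?:\.\d+)*",      # decimals and dotted version-like numbers
    r"(?m)^[ \t]*\d{1,2}\.[ \t]",  # numbered-list markers at line start
]


def _compile_protected(protected_patterns: list[str] | None) -> list[re.Pattern]:
    if protected_patterns is None:
        pats = [re.escape(a) for a in DEFAULT_PROTECTED_ABBREVIATIONS]
        pats += _DEFAULT_NUMERIC_PATTERNS
    else:
        pats = list(protected_patterns)
    return [re.compile(p) for p in pats]


_BOUNDARY_RE = re.compile(r"[.?!]+(?=\s)|\n[ \t]*\n")


def segment_sentences(
    doc_text: str,
    protected_patterns: list[str] | None = None,
    doc_id: str = "doc",
) -> list[Sentence]:
    """Split ``doc_text`` into sentences with exact source offsets.

    Boundaries are placed after runs of ``.?!`` followed by whitespace and
    at blank lines, computed on a masked copy in which every protected match
    is overwritten by a placeholder of identical length — offsets therefore
    carry over to the original text unchanged.  Concatenating the sentence
    slices with the skipped inter-sentence whitespace reconstructs
    ``doc_text`` exactly.
    """
    if _PLACEHOLDER in doc_text:
        raise PlaceholderCollisionError(
            "input text contains the reserved placeholder character U+E000"
        )
    if not doc_text.strip():
        return []

    masked = doc_text
    for pat in _compile_protected(protected_patterns):
        masked = pat.sub(lambda m: _PLACEHOLDER * len(m.group(0)), masked)
    assert len(masked) == len(doc_text)

    cut_points: list[int] = []
    for m in _BOUNDARY_RE.finditer(masked):
        cut_points.append(m.end())
    cut_points.append(len(doc_text))

    sentences: list[Sentence] = []
    prev = 0
    for cut in cut_points:
        chunk = doc_text[prev:cut]
        stripped = chunk.strip()
        if stripped:
            start = prev + (len(chunk) - len(chunk.lstrip()))
            end = start + len(stripped)
            sentences.append(
                Sentence(
                    doc_id=doc_id,
                    sent_index=len(sentences),
                    start=start,
                    end=end,
                    text=doc_text[start:end],
                )
            )
        prev = cut
    return sentences
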