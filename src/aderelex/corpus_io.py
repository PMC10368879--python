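"""Reading and writing paired ``.txt``/``.ann`` BRAT standoff files.

Only entity (``T``) and relation (``R``) lines are interpreted; event,
attribute, normalization, and note lines (``E``/``A``/``M``/``N``/``#``) are
tolerated and ignored.  Discontinuous entity spans (semicolon-separated
fragments) are collapsed to their ``[min(start), max(end))`` envelope and
flagged; writing such an entity re-emits the envelope only.
"""
from __future__ import annotations

import datetime
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .types import Corpus, Document, Entity, RelationAnnotation

__all__ = [
    "BratError",
    "BratParseError",
    "ConsistencyError",
    "DanglingReferenceError",
    "LoadReport",
    "read_brat",
    "write_brat",
    "load_corpus",
    "save_corpus",
]


class BratError(ValueError):
    """Base class for standoff-file errors."""


class BratParseError(BratError):
    """A standoff line could not be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, line: str, reason: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {reason}: {line!r}")


class ConsistencyError(BratError):
    """Annotation disagrees with the document text (offsets or surface)."""


class DanglingReferenceError(BratError):
    """A relation references an entity id absent from the document."""


_ENTITY_RE = re.compile(r"^(T\d+)\t(\S+) ([0-9; ]+)\t(.*)$", re.DOTALL)
_RELATION_RE = re.compile(r"^(R\d+)\t(\S+) Arg1:(T\d+) Arg2:(T\d+)\s*$")

# default filename convention: <patientid>_<YYYYMMDD>_<seq>.txt
DEFAULT_ID_PATTERN = re.compile(r"^(?P<patient>[^_]+)_(?P<date>\d{8})_(?P<seq>\d+)$")


def read_brat(text_content: str, ann_content: str, doc_id: str = "doc") -> Document:
    """Parse a ``.txt``/``.ann`` pair into a :class:`Document`.

    Raises :class:`BratParseError` on a malformed line,
    :class:`ConsistencyError` when an entity span falls outside the text or
    its surface disagrees with the text slice, and
    :class:`DanglingReferenceError` for relations naming unknown entities.
    """
    entities: list[Entity] = []
    relations: list[RelationAnnotation] = []
    entity_ids: set[str] = set()

    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip():
            continue
        head = line[0]
        if head == "T":
            m = _ENTITY_RE.match(line)
            if m is None:
                raise BratParseError(lineno, line, "malformed entity line")
            tid, label, span_field, surface = m.groups()
            fragments = []
            for frag in span_field.split(";"):
                parts = frag.split()
                if len(parts) != 2:
                    raise BratParseError(lineno, line, "malformed span fragment")
                try:
                    fragments.append((int(parts[0]), int(parts[1])))
                except ValueError:
                    raise BratParseError(lineno, line, "non-integer offset") from None
            start = min(s for s, _ in fragments)
            end = max(e for _, e in fragments)
            discontinuous = len(fragments) > 1
            if start < 0 or end > len(text_content) or start >= end:
                raise ConsistencyError(
                    f"{doc_id} line {lineno}: entity {tid} span [{start}, {end}) "
                    f"outside text of length {len(text_content)}"
                )
            slice_ = text_content[start:end]
            if not discontinuous and _norm_surface(slice_) != _norm_surface(surface):
                raise ConsistencyError(
                    f"{doc_id} line {lineno}: entity {tid} surface {surface!r} "
                    f"does not equal text slice {slice_!r}"
                )
            entities.append(
                Entity(
                    entity_id=tid,
                    label=label.upper(),
                    start=start,
                    end=end,
                    surface=slice_,
                    discontinuous=discontinuous,
                )
            )
            entity_ids.add(tid)
        elif head == "R":
            m = _RELATION_RE.match(line)
            if m is None:
                raise BratParseError(lineno, line, "malformed relation line")
            rid, rtype, a1, a2 = m.groups()
            relations.append(
                RelationAnnotation(
                    relation_id=rid, rel_type=rtype.upper(), arg1=a1, arg2=a2
                )
            )
        elif head in "EAMN#":
            continue
        else:
            raise BratParseError(lineno, line, "unknown annotation line type")

    for rel in relations:
        for arg in (rel.arg1, rel.arg2):
            if arg not in entity_ids:
                raise DanglingReferenceError(
                    f"{doc_id}: relation {rel.relation_id} references missing "
                    f"entity {arg}"
                )
    return Document(doc_id=doc_id, text=text_content, entities=entities, relations=relations)


def _norm_surface(s: str) -> str:
    # BRAT replaces newlines inside surfaces with spaces on write
    return s.replace("\n", " ")


def write_brat(doc: Document) -> tuple[str, str]:
    """Serialize a document to ``(text_content, ann_content)``.

    Entity lines are emitted sorted by start offset (then end, then id);
    ``read_brat(*write_brat(doc))`` reproduces ``doc`` for contiguous spans.
    """
    doc.validate()
    lines: list[str] = []
    for ent in sorted(doc.entities, key=lambda e: (e.start, e.end, e.entity_id)):
        lines.append(
            f"{ent.entity_id}\t{ent.label} {ent.start} {ent.end}\t"
            f"{_norm_surface(ent.surface)}"
        )
    for rel in doc.relations:
        lines.append(f"{rel.relation_id}\t{rel.rel_type} Arg1:{rel.arg1} Arg2:{rel.arg2}")
    ann = "\n".join(lines)
    if lines:
        ann += "\n"
    return doc.text, ann


@dataclass
class LoadReport:
    """What :func:`load_corpus` did: documents loaded, files skipped, errors."""

    n_loaded: int = 0
    skipped: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"loaded {self.n_loaded} document(s)"]
        for s in self.skipped:
            lines.append(f"skipped: {s}")
        for e in self.errors:
            lines.append(f"error: {e}")
        return "\n".join(lines)


def load_corpus(
    directory: str | Path,
    id_pattern: re.Pattern | str = DEFAULT_ID_PATTERN,
    corpus_id: str | None = None,
) -> tuple[Corpus, LoadReport]:
    """Load every paired ``*.txt``/``*.ann`` file under ``directory``.

    Patient id and note date are parsed from the stem via ``id_pattern``
    (default ``<patientid>_<YYYYMMDD>_<seq>``); stems that do not match get
    the whole stem as patient id and no date.  Unpaired files are skipped
    with a warning recorded in the report.  Documents are ordered by
    (patient_id, note_date, stem) and assigned per-patient order indices.
    """
    directory = Path(directory)
    if isinstance(id_pattern, str):
        id_pattern = re.compile(id_pattern)
    report = LoadReport()
    docs: list[Document] = []

    txt_files = {p.stem: p for p in sorted(directory.glob("*.txt"))}
    ann_files = {p.stem: p for p in sorted(directory.glob("*.ann"))}
    for stem in sorted(set(txt_files) | set(ann_files)):
        if stem not in txt_files or stem not in ann_files:
            missing = ".ann" if stem in txt_files else ".txt"
            msg = f"{stem}: missing companion {missing} file"
            warnings.warn(msg, stacklevel=2)
            report.skipped.append(msg)
            continue
        text = txt_files[stem].read_text(encoding="utf-8")
        ann = ann_files[stem].read_text(encoding="utf-8")
        try:
            doc = read_brat(text, ann, doc_id=stem)
        except BratError as exc:
            report.errors.append(f"{stem}: {exc}")
            continue
        m = id_pattern.match(stem)
        if m:
            doc.patient_id = m.group("patient")
            try:
                doc.note_date = datetime.datetime.strptime(
                    m.group("date"), "%Y%m%d"
                ).date()
            except (IndexError, ValueError):
                doc.note_date = None
        else:
            doc.patient_id = stem
        docs.append(doc)

    docs.sort(key=lambda d: (d.patient_id, d.note_date or datetime.date.min, d.doc_id))
    counters: dict[str, int] = {}
    for doc in docs:
        doc.order_index = counters.get(doc.patient_id, 0)
        counters[doc.patient_id] = doc.order_index + 1

    report.n_loaded = len(docs)
    corpus = Corpus(
        corpus_id=corpus_id or directory.name,
        documents=docs,
        provenance=str(directory),
    )
    return corpus, report


def save_corpus(corpus: Corpus, directory: str | Path) -> None:
    """Write each document of ``corpus`` as a ``.txt``/``.ann`` pair."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in corpus.documents:
        text, ann = write_brat(doc)
        (directory / f"{doc.doc_id}.txt").write_text(text, encoding="utf-8")
        (directory / f"{doc.doc_id}.ann").write_text(ann, encoding="utf-8")
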