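"""Core domain types shared across the pipeline.

Offsets are 0-based, half-open ``[start, end)`` throughout, matching the
BRAT standoff convention.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

#: Closed label set for curated annotations.  ``DATE`` is the generic label
#: emitted by the rule-based date tagger before a human (or the synthetic
#: generator) specializes it to DRUG_DATE / ADE_DATE.
ENTITY_LABELS = frozenset(
    {"DRUG", "ADE", "DRUG_DATE", "ADE_DATE", "CAUSAL_TERM", "GRADE", "DATE"}
)

RELATION_TYPES = frozenset(
    {"DRUG_ADE", "DRUG_DATE_LINK", "ADE_DATE_LINK", "CAUSAL_LINK", "GRADE_LINK"}
)


@dataclass(frozen=True, order=True)
class Entity:
    """A contiguous annotated mention in a document.

    ``discontinuous`` records that the underlying standoff line carried a
    multi-fragment span which was collapsed to its envelope on read.
    """

    entity_id: str
    label: str
    start: int
    end: int
    surface: str
    discontinuous: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"entity {self.entity_id}: invalid span [{self.start}, {self.end})"
            )

    @property
    def known_label(self) -> bool:
        return self.label in ENTITY_LABELS


@dataclass(frozen=True, order=True)
class RelationAnnotation:
    """A typed binary relation between two entities of one document."""

    relation_id: str
    rel_type: str
    arg1: str
    arg2: str


@dataclass
class Document:
    """One clinical note plus annotations and longitudinal metadata."""

    doc_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)
    patient_id: str = ""
    note_date: datetime.date | None = None
    order_index: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` on any invariant violation."""
        seen: set[str] = set()
        n = len(self.text)
        for ent in self.entities:
            if ent.entity_id in seen:
                raise ValueError(f"{self.doc_id}: duplicate entity id {ent.entity_id}")
            seen.add(ent.entity_id)
            if ent.end > n:
                raise ValueError(
                    f"{self.doc_id}: entity {ent.entity_id} span "
                    f"[{ent.start}, {ent.end}) outside text of length {n}"
                )
            if not ent.discontinuous and self.text[ent.start : ent.end] != ent.surface:
                raise ValueError(
                    f"{self.doc_id}: entity {ent.entity_id} surface mismatch: "
                    f"{self.text[ent.start:ent.end]!r} != {ent.surface!r}"
                )
        rel_ids: set[str] = set()
        for rel in self.relations:
            if rel.relation_id in rel_ids:
                raise ValueError(
                    f"{self.doc_id}: duplicate relation id {rel.relation_id}"
                )
            rel_ids.add(rel.relation_id)
            for arg in (rel.arg1, rel.arg2):
                if arg not in seen:
                    raise ValueError(
                        f"{self.doc_id}: relation {rel.relation_id} references "
                        f"missing entity {arg}"
                    )

    def entity_by_id(self, entity_id: str) -> Entity:
        for ent in self.entities:
            if ent.entity_id == entity_id:
                return ent
        raise KeyError(entity_id)

    def copy(self) -> "Document":
        return replace(
            self, entities=list(self.entities), relations=list(self.relations)
        )


@dataclass
class Corpus:
    """An ordered collection of documents from one source."""

    corpus_id: str
    documents: list[Document] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def validate(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.corpus_id}: duplicate doc_ids")
        for doc in self.documents:
            doc.validate()


@dataclass(frozen=True)
class Sentence:
    """A sentence span of one document; ``text == doc_text[start:end]``."""

    doc_id: str
    sent_index: int
    start: int
    end: int
    text: str
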