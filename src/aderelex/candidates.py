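"""Candidate drug-ADE pair construction, labeling, and deduplication.

Every within-sentence (drug mention, ADE mention) combination becomes one
candidate; a candidate is positive iff the gold relations contain a
DRUG_ADE link for that exact entity pair, otherwise negative (negatives are
derived by subtracting the annotated positives from the full cross
product).  Cross-sentence gold relations contribute zero candidates.

The classifier input span runs from the start of the earlier-starting
entity to the end of the later-ending one: the drug, the ADE, and
everything between.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .preprocess import segment_sentences
from .types import Corpus, Document, Entity, RelationAnnotation, Sentence

__all__ = [
    "CandidateRelation",
    "RelationDataset",
    "DedupConflictError",
    "enumerate_pairs",
    "extract_input_span",
    "deduplicate",
    "build_dataset",
    "document_candidates",
    "make_dedup_key",
    "save_dataset",
    "load_dataset",
]

#: combinatorial blow-up guard threshold per sentence
MANY_ENTITIES = 10


class DedupConflictError(ValueError):
    """Two candidates share a dedup key but carry different gold labels."""


@dataclass(frozen=True)
class CandidateRelation:
    candidate_id: str
    doc_id: str
    sent_index: int
    drug: Entity
    ade: Entity
    label: int  # 1 positive, 0 negative
    input_span: str
    dedup_key: str
    sentence_text: str = ""
    degenerate: bool = False  # drug and ADE spans overlap


@dataclass
class RelationDataset:
    candidates: list[CandidateRelation] = field(default_factory=list)
    source_corpus: str = ""

    @property
    def counts(self) -> tuple[int, int]:
        pos = sum(c.label == 1 for c in self.candidates)
        return pos, len(self.candidates) - pos

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def spans(self) -> list[str]:
        return [c.input_span for c in self.candidates]

    def labels(self) -> list[int]:
        return [c.label for c in self.candidates]


def _collapse_ws(s: str) -> str:
    return " ".join(s.split())


def make_dedup_key(drug_surface: str, input_span: str, ade_surface: str, sentence_text: str) -> str:
    """Case-folded, whitespace-collapsed key over (drug, span, ade, sentence)."""
    parts = (drug_surface, input_span, ade_surface, sentence_text)
    return "||".join(_collapse_ws(p.casefold()) for p in parts)


def extract_input_span(sentence: Sentence, drug: Entity, ade: Entity) -> tuple[str, bool]:
    """Return (span, degenerate): sentence slice covering both entities.

    The span runs from the earlier-starting entity's start to the
    later-ending entity's end.  Overlapping drug/ADE spans still yield the
    envelope but are flagged degenerate.
    """
    for ent in (drug, ade):
        if ent.start < sentence.start or ent.end > sentence.end:
            raise ValueError(
                f"entity {ent.entity_id} [{ent.start},{ent.end}) outside sentence "
                f"[{sentence.start},{sentence.end})"
            )
    lo = min(drug.start, ade.start) - sentence.start
    hi = max(drug.end, ade.end) - sentence.start
    degenerate = drug.start < ade.end and ade.start < drug.end
    return sentence.text[lo:hi], degenerate


def enumerate_pairs(
    sentence: Sentence,
    entities: list[Entity],
    gold: list[RelationAnnotation] | set[RelationAnnotation],
) -> list[CandidateRelation]:
    """Emit all |drugs| x |ADEs| candidates for one sentence, labeled from gold.

    ``entities`` must already be restricted to this sentence.  Order is
    deterministic: by drug start offset, then ADE start offset.
    """
    drugs = sorted(
        (e for e in entities if e.label == "DRUG"), key=lambda e: (e.start, e.end)
    )
    ades = sorted(
        (e for e in entities if e.label == "ADE"), key=lambda e: (e.start, e.end)
    )
    if len(drugs) > MANY_ENTITIES or len(ades) > MANY_ENTITIES:
        warnings.warn(
            f"{sentence.doc_id} sentence {sentence.sent_index}: "
            f"{len(drugs)} drugs x {len(ades)} ADEs candidate blow-up",
            stacklevel=2,
        )
    positive_pairs = {
        (r.arg1, r.arg2) for r in gold if r.rel_type == "DRUG_ADE"
    }
    out: list[CandidateRelation] = []
    for drug in drugs:
        for ade in ades:
            span, degenerate = extract_input_span(sentence, drug, ade)
            label = int((drug.entity_id, ade.entity_id) in positive_pairs)
            cid = f"{sentence.doc_id}:s{sentence.sent_index}:{drug.entity_id}-{ade.entity_id}"
            out.append(
                CandidateRelation(
                    candidate_id=cid,
                    doc_id=sentence.doc_id,
                    sent_index=sentence.sent_index,
                    drug=drug,
                    ade=ade,
                    label=label,
                    input_span=span,
                    dedup_key=make_dedup_key(drug.surface, span, ade.surface, sentence.text),
                    sentence_text=sentence.text,
                    degenerate=degenerate,
                )
            )
    return out


def document_candidates(
    doc: Document, sentences: list[Sentence] | None = None
) -> list[CandidateRelation]:
    """Enumerate labeled candidates for every sentence of one document."""
    if sentences is None:
        sentences = segment_sentences(doc.text, doc_id=doc.doc_id)
    by_id = {e.entity_id: e for e in doc.entities}
    out: list[CandidateRelation] = []
    for sent in sentences:
        in_sent = [
            e for e in doc.entities if e.start >= sent.start and e.end <= sent.end
        ]
        ids = {e.entity_id for e in in_sent}
        gold = [
            r
            for r in doc.relations
            if r.rel_type == "DRUG_ADE" and r.arg1 in ids and r.arg2 in ids
        ]
        # sanity: DRUG_ADE args must be a (DRUG, ADE) pair
        for r in gold:
            if by_id[r.arg1].label != "DRUG" or by_id[r.arg2].label != "ADE":
                raise ValueError(
                    f"{doc.doc_id}: relation {r.relation_id} arguments are not (DRUG, ADE)"
                )
        out.extend(enumerate_pairs(sent, in_sent, gold))
    return out


def build_dataset(
    corpus: Corpus,
    dedup: bool = True,
    include_degenerate: bool = False,
) -> RelationDataset:
    """Candidate dataset for a whole corpus (deduplicated by default)."""
    cands: list[CandidateRelation] = []
    for doc in corpus.documents:
        cands.extend(document_candidates(doc))
    if not include_degenerate:
        cands = [c for c in cands if not c.degenerate]
    ds = RelationDataset(candidates=cands, source_corpus=corpus.corpus_id)
    return deduplicate(ds) if dedup else ds


def deduplicate(dataset: RelationDataset) -> RelationDataset:
    """Keep the first candidate per dedup key (idempotent).

    Raises :class:`DedupConflictError` if two candidates with the same key
    disagree on the label — impossible under consistent gold annotation.
    """
    seen: dict[str, CandidateRelation] = {}
    kept: list[CandidateRelation] = []
    for cand in dataset.candidates:
        prev = seen.get(cand.dedup_key)
        if prev is None:
            seen[cand.dedup_key] = cand
            kept.append(cand)
        elif prev.label != cand.label:
            raise DedupConflictError(
                f"conflicting labels for duplicate candidates "
                f"{prev.candidate_id} (label {prev.label}) and "
                f"{cand.candidate_id} (label {cand.label})"
            )
    return RelationDataset(candidates=kept, source_corpus=dataset.source_corpus)


_COLUMNS = [
    "candidate_id",
    "doc_id",
    "sent_index",
    "drug_surface",
    "ade_surface",
    "label",
    "input_span",
    "sentence_text",
    "dedup_key",
    "degenerate",
]


def save_dataset(dataset: RelationDataset, path: str | Path) -> None:
    """Write TSV (one row per candidate) plus a JSON count manifest."""
    path = Path(path)
    rows = [
        {
            "candidate_id": c.candidate_id,
            "doc_id": c.doc_id,
            "sent_index": c.sent_index,
            "drug_surface": c.drug.surface,
            "ade_surface": c.ade.surface,
            "label": c.label,
            "input_span": c.input_span,
            "sentence_text": c.sentence_text,
            "dedup_key": c.dedup_key,
            "degenerate": int(c.degenerate),
        }
        for c in dataset.candidates
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
    pos, neg = dataset.counts
    manifest = {
        "source_corpus": dataset.source_corpus,
        "n_positive": pos,
        "n_negative": neg,
        "n_total": len(dataset),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")


def load_dataset(path: str | Path, source_corpus: str = "") -> RelationDataset:
    """Read a dataset TSV written by :func:`save_dataset`.

    Entity offsets are not stored in the TSV; loaded candidates carry
    surface-only placeholder entities sufficient for training/evaluation.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"label": int})
    cands = []
    for _, row in df.iterrows():
        drug = Entity("T1", "DRUG", 0, max(1, len(row["drug_surface"])), row["drug_surface"])
        ade = Entity("T2", "ADE", 0, max(1, len(row["ade_surface"])), row["ade_surface"])
        cands.append(
            CandidateRelation(
                candidate_id=row["candidate_id"],
                doc_id=row["doc_id"],
                sent_index=int(row["sent_index"]),
                drug=drug,
                ade=ade,
                label=int(row["label"]),
                input_span=row["input_span"],
                dedup_key=row["dedup_key"],
                sentence_text=row["sentence_text"],
                degenerate=bool(int(row["degenerate"])),
            )
        )
    return RelationDataset(candidates=cands, source_corpus=source_corpus)
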