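"""Synthetic clinical-note corpora with gold BRAT annotations.

Notes are assembled from templated sentences so that every pipeline stage
is testable offline: drug/ADE mentions come only from the packaged
lexicons, dates follow the rule-based tagger's formats, whitespace noise
and mid-sentence line breaks are injected only outside entity spans (gold
offsets stay exact), boilerplate sentences repeat verbatim across notes,
and a minority of relations span sentences (planted, flagged, and excluded
from within-sentence candidates).

The label signal is a connector slot between the ADE and the drug:
positive pairs realize a causal cue there with probability
``signal_strength`` (a neutral connector otherwise) and negative pairs the
reverse — so ``signal_strength = 1`` is perfectly separable and the dial
degrades gracefully.  Multi-entity sentences plant the 2-drugs x 2-ADEs
configuration with exactly one gold pair.

Everything derives from one seeded generator: (config, seed) -> byte-
identical corpora.
"""
from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .candidates import make_dedup_key
from .tagging import default_lexicon
from .types import Corpus, Document, Entity, RelationAnnotation

__all__ = [
    "NoiseConfig",
    "SynthConfig",
    "SynthManifest",
    "generate_corpus",
    "make_paired_corpora",
    "preset",
    "PRESETS",
    "MASTER_CUES",
]

MASTER_CUES = [
    "attributed to",
    "secondary to",
    "due to",
    "caused by",
    "related to",
    "associated with",
    "consistent with",
    "induced",
]

#: connector phrases carrying no causal signal; shared by both classes
NEUTRAL_CONNECTORS = [
    "monitored during",
    "noted before",
    "stable on",
    "unchanged with",
    "present prior to",
    "followed alongside",
]

_FILLER_SENTENCES = [
    "Vitals were stable and the plan was discussed",
    "The patient tolerated the visit well",
    "Labs were reviewed and counseling was provided",
    "Follow up was arranged in clinic",
    "No new complaints were reported today",
    "Imaging was ordered and results are pending",
]

_LONG_FILLER = (
    "The care team met at length to review the overall treatment course, "
    "the outstanding laboratory work, the pending imaging studies, the goals "
    "of care conversation, and the scheduling constraints raised by the family "
    "during the most recent telephone encounter"
)

_BOILERPLATE_PARAGRAPH = "Allergies and medication list were reconciled"


@dataclass(frozen=True)
class NoiseConfig:
    p_extra_whitespace: float = 0.1
    p_brand_name: float = 0.2
    p_abbreviation: float = 0.1
    p_mid_sentence_linebreak: float = 0.05


@dataclass
class SynthConfig:
    n_patients: int = 10
    notes_per_patient: tuple[int, int] = (2, 4)
    sentences_per_note: tuple[int, int] = (3, 7)
    p_entity_sentence: float = 0.6
    p_positive_sentence: float = 0.3
    signal_strength: float = 0.9
    causal_lexicon: list[str] = field(default_factory=lambda: MASTER_CUES[:4])
    p_multi_entity_sentence: float = 0.1
    p_cross_sentence_relation: float = 0.05
    p_boilerplate_repeat: float = 0.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    target_ratio: float | None = None  # positive:negative; overrides p_positive_sentence
    p_long_sentence: float = 0.02
    seed: int = 0
    corpus_id: str = "synthetic"

    def __post_init__(self) -> None:
        probs = [
            self.p_entity_sentence,
            self.p_positive_sentence,
            self.signal_strength,
            self.p_multi_entity_sentence,
            self.p_cross_sentence_relation,
            self.p_boilerplate_repeat,
            self.p_long_sentence,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not self.causal_lexicon:
            raise ValueError("causal_lexicon must be non-empty")

    def effective_p_positive(self) -> float:
        """Single-pair positive probability that realizes ``target_ratio``.

        A multi-entity sentence contributes 1 positive and 3 negatives, a
        single-pair sentence 1/0 or 0/1; solving the expected ratio r with
        multi fraction m gives p = (r(1 + 2m) - m) / ((1 - m)(1 + r)).
        """
        if self.target_ratio is None:
            return self.p_positive_sentence
        r = self.target_ratio
        m = self.p_multi_entity_sentence
        if m >= 1.0:
            raise ValueError("target_ratio unsatisfiable: all sentences multi-entity")
        p = (r * (1 + 2 * m) - m) / ((1 - m) * (1 + r))
        if not 0.0 <= p <= 1.0:
            raise ValueError(
                f"target_ratio {r} unsatisfiable with "
                f"p_multi_entity_sentence={m}: needs single-positive rate {p:.3f}"
            )
        return p


@dataclass
class _SentenceSpec:
    """One templated sentence: local entity spans + gold pair indices."""

    text: str
    entities: list[tuple[str, int, int, str]]  # (label, start, end, surface)
    gold_pairs: list[tuple[int, int]]  # (drug entity idx, ade entity idx)
    kind: str  # pos / neg / multi / filler / date / grade / cross_drug / cross_ade

    def n_drugs(self) -> int:
        return sum(1 for e in self.entities if e[0] == "DRUG")

    def n_ades(self) -> int:
        return sum(1 for e in self.entities if e[0] == "ADE")


@dataclass
class SynthManifest:
    """Exact ground truth for one generated corpus."""

    corpus_id: str
    seed: int
    documents: list[dict] = field(default_factory=list)
    n_candidates: int = 0
    n_positive: int = 0
    n_negative: int = 0
    n_unique: int = 0
    n_unique_positive: int = 0
    n_unique_negative: int = 0
    n_cross_sentence_relations: int = 0
    realized_ratio: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


class _Builder:
    """Accumulates one sentence, tracking entity offsets through noise."""

    def __init__(self, rng: random.Random, noise: NoiseConfig):
        self.rng = rng
        self.noise = noise
        self.parts: list[str] = []
        self.cursor = 0
        self.entities: list[tuple[str, int, int, str]] = []

    def _gap(self) -> None:
        if not self.parts:
            return
        sep = " "
        if self.rng.random() < self.noise.p_extra_whitespace:
            sep = "  "
        elif self.rng.random() < self.noise.p_mid_sentence_linebreak:
            sep = "\n"
        self.parts.append(sep)
        self.cursor += len(sep)

    def words(self, text: str) -> "_Builder":
        self._gap()
        self.parts.append(text)
        self.cursor += len(text)
        return self

    def entity(self, label: str, surface: str) -> "_Builder":
        self._gap()
        self.entities.append((label, self.cursor, self.cursor + len(surface), surface))
        self.parts.append(surface)
        self.cursor += len(surface)
        return self

    def punct(self, ch: str = ".") -> "_Builder":
        self.parts.append(ch)
        self.cursor += len(ch)
        return self

    def build(self, gold_pairs: list[tuple[int, int]], kind: str) -> _SentenceSpec:
        return _SentenceSpec(
            text="".join(self.parts), entities=self.entities, gold_pairs=gold_pairs, kind=kind
        )


class _Generator:
    def __init__(self, config: SynthConfig):
        self.cfg = config
        self.rng = random.Random(config.seed)
        drug_lex = default_lexicon("DRUG")
        ade_lex = default_lexicon("ADE")
        self.drug_entries = sorted(
            (canon, sorted(vs)) for canon, vs in drug_lex.entries.items()
        )
        self.ade_entries = sorted(
            (canon, sorted(vs)) for canon, vs in ade_lex.entries.items()
        )
        self.registry: list[_SentenceSpec] = []  # boilerplate source
        self._entity_texts: set[str] = set()

    # -- surface pickers ---------------------------------------------------
    def _drug_surface(self) -> str:
        canon, variants = self.rng.choice(self.drug_entries)
        brands = [v for v in variants if v != canon]
        if brands and self.rng.random() < self.cfg.noise.p_brand_name:
            return self.rng.choice(brands)
        return canon

    def _two_drugs(self) -> tuple[str, str]:
        (c1, v1), (c2, v2) = self.rng.sample(self.drug_entries, 2)
        return c1, c2

    def _ade_surface(self) -> str:
        _, variants = self.rng.choice(self.ade_entries)
        return self.rng.choice(variants)

    def _two_ades(self) -> tuple[str, str]:
        picks = self.rng.sample(self.ade_entries, 2)
        return self.rng.choice(picks[0][1]), self.rng.choice(picks[1][1])

    def _connector(self, causal: bool) -> tuple[str, bool]:
        """Return (connector phrase, is_cue)."""
        if causal:
            return self.rng.choice(self.cfg.causal_lexicon), True
        return self.rng.choice(NEUTRAL_CONNECTORS), False

    def _date(self) -> str:
        y = self.rng.randint(2011, 2018)
        mth = self.rng.randint(1, 12)
        d = self.rng.randint(1, 28)
        style = self.rng.randrange(3)
        if style == 0:
            return f"{mth}/{d}/{y}"
        if style == 1:
            return f"{y}-{mth:02d}-{d:02d}"
        month_names = [
            "January", "February", "March", "April", "May", "June", "July",
            "August", "September", "October", "November", "December",
        ]
        return f"{month_names[mth - 1]} {d}, {y}"

    # -- sentence templates ------------------------------------------------
    def _mark_cue(self, b: _Builder, connector: str) -> None:
        # call immediately after b.words(connector): span = cursor - len .. cursor
        b.entities.append(
            ("CAUSAL_TERM", b.cursor - len(connector), b.cursor, connector)
        )

    def _day_token(self) -> str:
        # per-sentence entropy OUTSIDE every input span, so otherwise identical
        # sentences with different gold labels cannot collide on dedup keys
        return f"on day {self.rng.randint(2, 99)}"

    def _pair_sentence(self, positive: bool) -> _SentenceSpec:
        """Single drug-ADE co-mention; the connector carries the signal."""
        cue_slot = positive == (self.rng.random() < self.cfg.signal_strength)
        connector, is_cue = self._connector(cue_slot)
        b = _Builder(self.rng, self.cfg.noise)
        drug = self._drug_surface()
        ade = self._ade_surface()
        if is_cue and connector == "induced":
            # infix form: "<drug>-induced <ade>"
            b.words("On review,")
            b.entity("DRUG", drug)
            b.punct("-")
            cue_start = b.cursor
            b.parts.append("induced")
            b.cursor += len("induced")
            b.entity("ADE", ade)
            b.words("was seen")
            b.words(self._day_token())
            b.entities.append(("CAUSAL_TERM", cue_start, cue_start + 7, "induced"))
            drug_idx, ade_idx = 0, 1
        else:
            b.words("On review,")
            b.entity("ADE", ade)
            b.words("was")
            b.words(connector)
            if is_cue:
                self._mark_cue(b, connector)
            b.entity("DRUG", drug)
            ade_idx = 0
            drug_idx = len(b.entities) - 1
            b.words("therapy")
            b.words(self._day_token())
        b.punct(".")
        gold = [(drug_idx, ade_idx)] if positive else []
        return b.build(gold, "pos" if positive else "neg")

    def _multi_sentence(self, with_gold: bool) -> _SentenceSpec:
        """2 drugs x 2 ADEs, exactly one gold pair (the d1/d2/a1/a2 case)."""
        d_other, d_pos = self._two_drugs()
        a_other, a_pos = self._two_ades()
        cue_slot = with_gold and (self.rng.random() < self.cfg.signal_strength)
        connector, is_cue = self._connector(cue_slot)
        if connector == "induced":
            connector, is_cue = "due to", True
        b = _Builder(self.rng, self.cfg.noise)
        b.entity("DRUG", d_other)
        b.words("and")
        b.entity("ADE", a_other)
        b.words("were reviewed, then")
        b.entity("ADE", a_pos)
        b.words("was")
        b.words(connector)
        if is_cue:
            self._mark_cue(b, connector)
        b.entity("DRUG", d_pos)
        drug_pos_idx = len(b.entities) - 1
        b.words(self._day_token())
        b.punct(".")
        gold = [(drug_pos_idx, 2)] if with_gold else []
        return b.build(gold, "multi")

    def _filler_sentence(self) -> _SentenceSpec:
        b = _Builder(self.rng, self.cfg.noise)
        roll = self.rng.random()
        if roll < self.cfg.p_long_sentence:
            b.words(_LONG_FILLER)
        elif roll < self.cfg.p_long_sentence + 0.15:
            # drug-date sentence: DRUG + DRUG_DATE + link, no candidates
            b.entity("DRUG", self._drug_surface())
            b.words("was started on")
            b.entity("DRUG_DATE", self._date())
            spec = b.punct(".").build([], "date")
            return spec
        elif roll < self.cfg.p_long_sentence + 0.25:
            b.words("Severity was")
            b.entity("GRADE", f"grade {self.rng.randint(1, 4)}")
            b.words("at that visit")
        else:
            b.words(self.rng.choice(_FILLER_SENTENCES))
            if self.rng.random() < self.cfg.noise.p_abbreviation:
                b.words("b.i.d. as documented")
        return b.punct(".").build([], "filler")

    def _cross_pair(self) -> tuple[_SentenceSpec, _SentenceSpec]:
        b1 = _Builder(self.rng, self.cfg.noise)
        b1.entity("DRUG", self._drug_surface()).words("was continued").punct(".")
        b2 = _Builder(self.rng, self.cfg.noise)
        b2.words("Later,").entity("ADE", self._ade_surface()).words("was documented").punct(".")
        return b1.build([], "cross_drug"), b2.build([], "cross_ade")

    def _fresh_sentence(self, kind: str, multi_with_gold: bool) -> _SentenceSpec:
        """Build a sentence; entity-bearing texts are resampled to be unique
        so duplicate dedup keys can only come from boilerplate repeats."""
        for _ in range(100):
            if kind == "multi":
                spec = self._multi_sentence(multi_with_gold)
            elif kind == "pos":
                spec = self._pair_sentence(True)
            elif kind == "neg":
                spec = self._pair_sentence(False)
            else:
                return self._filler_sentence()
            norm = " ".join(spec.text.split()).casefold()  # match dedup-key folding
            if norm not in self._entity_texts:
                self._entity_texts.add(norm)
                return spec
        raise RuntimeError("could not generate a unique entity sentence")

    # -- corpus assembly ---------------------------------------------------
    def generate(self) -> tuple[Corpus, SynthManifest]:
        cfg = self.cfg
        p_pos = cfg.effective_p_positive()
        multi_with_gold = cfg.target_ratio is not None or cfg.p_positive_sentence > 0

        # note skeleton first so type quotas are exact
        skeleton = []  # (patient, note_idx, n_sentences)
        for p in range(cfg.n_patients):
            n_notes = self.rng.randint(*cfg.notes_per_patient)
            for k in range(n_notes):
                skeleton.append((p, k, self.rng.randint(*cfg.sentences_per_note)))
        total = sum(s for _, _, s in skeleton)

        boiler_flags = [
            self.rng.random() < cfg.p_boilerplate_repeat for _ in range(total)
        ]
        boiler_flags[0] = False  # registry empty at the first sentence
        n_fresh = sum(not f for f in boiler_flags)
        n_entity = round(n_fresh * cfg.p_entity_sentence)
        n_multi = round(n_entity * cfg.p_multi_entity_sentence)
        n_single = n_entity - n_multi
        n_pos = round(n_single * p_pos)
        types = (
            ["multi"] * n_multi
            + ["pos"] * n_pos
            + ["neg"] * (n_single - n_pos)
            + ["filler"] * (n_fresh - n_entity)
        )
        self.rng.shuffle(types)
        type_iter = iter(types)

        docs: list[Document] = []
        doc_manifests: list[dict] = []
        all_keys: list[tuple[str, int]] = []  # (dedup_key, label)
        n_cand = n_cand_pos = n_cross = 0
        slot = 0
        base_date = 20170101

        for patient, note_idx, n_sent in skeleton:
            specs: list[_SentenceSpec] = []
            for _ in range(n_sent):
                if boiler_flags[slot] and self.registry:
                    specs.append(self.registry[self.rng.randrange(len(self.registry))])
                else:
                    t = next(type_iter)
                    spec = self._fresh_sentence(t, multi_with_gold)
                    specs.append(spec)
                    self.registry.append(spec)
                slot += 1

            cross_here = (
                self.rng.random() < cfg.p_cross_sentence_relation
                and cfg.p_positive_sentence + cfg.p_multi_entity_sentence > 0
            )
            if cross_here:
                s_drug, s_ade = self._cross_pair()
                specs.extend([s_drug, s_ade])

            doc = self._assemble(patient, note_idx, specs, base_date, cross_here)
            docs.append(doc)

            # per-document accounting
            sent_infos = []
            for spec in specs:
                nd, na = spec.n_drugs(), spec.n_ades()
                sent_infos.append(
                    {
                        "n_drugs": nd,
                        "n_ades": na,
                        "expected_candidates": nd * na,
                        "n_positive": len(spec.gold_pairs),
                        "kind": spec.kind,
                    }
                )
                n_cand += nd * na
                n_cand_pos += len(spec.gold_pairs)
                all_keys.extend(_spec_keys(spec))
            if cross_here:
                n_cross += 1
            doc_manifests.append(
                {
                    "doc_id": doc.doc_id,
                    "n_entities": len(doc.entities),
                    "n_relations": len(doc.relations),
                    "cross_sentence": cross_here,
                    "sentences": sent_infos,
                }
            )

        unique: dict[str, int] = {}
        for key, label in all_keys:
            unique.setdefault(key, label)
        uniq_pos = sum(v for v in unique.values())
        uniq_neg = len(unique) - uniq_pos

        manifest = SynthManifest(
            corpus_id=cfg.corpus_id,
            seed=cfg.seed,
            documents=doc_manifests,
            n_candidates=n_cand,
            n_positive=n_cand_pos,
            n_negative=n_cand - n_cand_pos,
            n_unique=len(unique),
            n_unique_positive=uniq_pos,
            n_unique_negative=uniq_neg,
            n_cross_sentence_relations=n_cross,
            realized_ratio=(uniq_pos / uniq_neg) if uniq_neg else float("inf"),
        )
        if cfg.target_ratio is not None and uniq_neg:
            ratio = uniq_pos / uniq_neg
            if abs(ratio - cfg.target_ratio) > 0.1 * cfg.target_ratio:
                raise ValueError(
                    f"realized ratio {ratio:.3f} misses target "
                    f"{cfg.target_ratio:.3f} by more than 10%; "
                    "increase corpus size or adjust probabilities"
                )
        corpus = Corpus(
            corpus_id=cfg.corpus_id,
            documents=docs,
            provenance=f"synthetic seed={cfg.seed}",
        )
        corpus.validate()
        return corpus, manifest

    def _assemble(
        self,
        patient: int,
        note_idx: int,
        specs: list[_SentenceSpec],
        base_date: int,
        cross_here: bool,
    ) -> Document:
        parts: list[str] = []
        cursor = 0
        entities: list[Entity] = []
        relations: list[RelationAnnotation] = []
        offsets: list[list[int]] = []  # absolute entity index per spec
        eid = rid = 0
        for i, spec in enumerate(specs):
            if parts:
                sep = "\n\n" if self.rng.random() < 0.15 else " "
                parts.append(sep)
                cursor += len(sep)
            idx_map = []
            for label, s, e, surface in spec.entities:
                eid += 1
                entities.append(
                    Entity(f"T{eid}", label, cursor + s, cursor + e, surface)
                )
                idx_map.append(len(entities) - 1)
            offsets.append(idx_map)
            for d_i, a_i in spec.gold_pairs:
                rid += 1
                relations.append(
                    RelationAnnotation(
                        f"R{rid}",
                        "DRUG_ADE",
                        entities[idx_map[d_i]].entity_id,
                        entities[idx_map[a_i]].entity_id,
                    )
                )
            if spec.kind == "date":
                drug_i = next(
                    j for j in idx_map if entities[j].label == "DRUG"
                )
                date_i = next(
                    j for j in idx_map if entities[j].label == "DRUG_DATE"
                )
                rid += 1
                relations.append(
                    RelationAnnotation(
                        f"R{rid}",
                        "DRUG_DATE_LINK",
                        entities[drug_i].entity_id,
                        entities[date_i].entity_id,
                    )
                )
            parts.append(spec.text)
            cursor += len(spec.text)

        if cross_here:
            # last two specs are the planted cross-sentence drug/ADE pair
            drug_i = offsets[-2][0]
            ade_i = offsets[-1][0]
            rid += 1
            relations.append(
                RelationAnnotation(
                    f"R{rid}",
                    "DRUG_ADE",
                    entities[drug_i].entity_id,
                    entities[ade_i].entity_id,
                )
            )

        date = base_date + note_idx * 7 + (patient % 28)
        doc = Document(
            doc_id=f"p{patient:03d}_{date}_{note_idx:03d}",
            text="".join(parts),
            entities=entities,
            relations=relations,
            patient_id=f"p{patient:03d}",
            order_index=note_idx,
        )
        return doc


def _spec_keys(spec: _SentenceSpec) -> list[tuple[str, int]]:
    """Dedup keys + labels for all candidates a sentence will produce."""
    drugs = [
        (i, e) for i, e in enumerate(spec.entities) if e[0] == "DRUG"
    ]
    ades = [(i, e) for i, e in enumerate(spec.entities) if e[0] == "ADE"]
    gold = set(spec.gold_pairs)
    keys = []
    for di, d in drugs:
        for ai, a in ades:
            lo = min(d[1], a[1])
            hi = max(d[2], a[2])
            span = spec.text[lo:hi]
            key = make_dedup_key(d[3], span, a[3], spec.text)
            keys.append((key, int((di, ai) in gold)))
    return keys


def generate_corpus(config: SynthConfig) -> tuple[Corpus, SynthManifest]:
    """Generate a corpus plus its exact ground-truth manifest."""
    return _Generator(config).generate()


def make_paired_corpora(
    config_a: SynthConfig, config_b: SynthConfig, cue_overlap: float
) -> tuple[tuple[Corpus, SynthManifest], tuple[Corpus, SynthManifest]]:
    """Two corpora whose causal-cue lexicons share the given fraction.

    Emulates differing annotation guidelines between sources: corpus A uses
    the first half of the master cue list, corpus B shares
    ``round(cue_overlap * |A|)`` of A's cues and draws the rest from the
    disjoint second half.
    """
    if not 0.0 <= cue_overlap <= 1.0:
        raise ValueError("cue_overlap must lie in [0, 1]")
    half = len(MASTER_CUES) // 2
    cues_a = MASTER_CUES[:half]
    n_shared = round(cue_overlap * half)
    cues_b = cues_a[:n_shared] + MASTER_CUES[half : half + (half - n_shared)]
    config_a = _with_cues(config_a, cues_a, "A")
    config_b = _with_cues(config_b, cues_b, "B")
    return generate_corpus(config_a), generate_corpus(config_b)


def _with_cues(cfg: SynthConfig, cues: list[str], suffix: str) -> SynthConfig:
    out = SynthConfig(**{**asdict(cfg), "noise": cfg.noise, "causal_lexicon": list(cues)})
    if out.corpus_id == "synthetic":
        out.corpus_id = f"synthetic-{suffix}"
    return out


PRESETS: dict[str, dict] = {
    # class ratio ~ 189:698
    "ici-like": dict(
        n_patients=47,
        notes_per_patient=(2, 4),
        sentences_per_note=(3, 7),
        target_ratio=189 / 698,
        p_multi_entity_sentence=0.1,
        signal_strength=0.9,
        corpus_id="ici-like",
    ),
    # 505 single-note records, class ratio ~ 1355:865
    "n2c2-like": dict(
        n_patients=505,
        notes_per_patient=(1, 1),
        sentences_per_note=(3, 6),
        target_ratio=1355 / 865,
        p_multi_entity_sentence=0.1,
        signal_strength=0.9,
        corpus_id="n2c2-like",
    ),
}


def preset(name: str, seed: int = 0, **overrides) -> SynthConfig:
    """Shipped preset configs: ``ici-like`` and ``n2c2-like``."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kwargs = {**PRESETS[name], **overrides, "seed": seed}
    return SynthConfig(**kwargs)
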