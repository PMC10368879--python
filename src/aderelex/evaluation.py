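"""Scoring, intra-/inter-corpus protocols, agreement statistics, cluster maps.

Reported precision/recall/F are positive-class scores: the minority
positive class (drug induced the ADE) is the detection target.  Five-fold
cross-validation results are pooled (micro) over folds by default.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.model_selection import StratifiedKFold, train_test_split

from .candidates import RelationDataset
from .models import TrainConfig, get_model, predictions_from_scores
from .models.base import Prediction
from .types import Corpus

__all__ = [
    "DEFAULT_SEED",
    "EvalReport",
    "AgreementMatrix",
    "IaaReport",
    "score",
    "run_intra",
    "run_inter",
    "cohen_kappa",
    "pairwise_f_agreement",
    "agreement_cluster_map",
    "render_cluster_map",
]

#: fixed default seed recorded in every report
DEFAULT_SEED = 1218679

PROTOCOLS = ("intra_cv", "intra_fixed", "inter")


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    tn: int
    model_id: str = ""
    train_corpus: str = ""
    test_corpus: str = ""
    protocol: str = ""
    seed: int = DEFAULT_SEED
    undefined_precision: bool = False
    undefined_recall: bool = False

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        self.undefined_precision = (self.tp + self.fp) == 0
        self.undefined_recall = (self.tp + self.fn) == 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "model_id": self.model_id,
            "train_corpus": self.train_corpus,
            "test_corpus": self.test_corpus,
            "protocol": self.protocol,
            "seed": self.seed,
            "undefined_precision": self.undefined_precision,
            "undefined_recall": self.undefined_recall,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def score(
    predictions: Sequence[Prediction],
    gold: dict[str, int],
    **report_fields,
) -> EvalReport:
    """Confusion counts and positive-class P/R/F for one prediction set.

    ``gold`` maps candidate_id -> label; a prediction must exist for every
    gold candidate.
    """
    by_id = {p.candidate_id: p for p in predictions}
    missing = sorted(set(gold) - set(by_id))
    if missing:
        raise ValueError(f"missing predictions for {len(missing)} candidates: {missing[:5]}")
    tp = fp = fn = tn = 0
    for cid, y_true in gold.items():
        y_pred = by_id[cid].y
        if y_true == 1 and y_pred == 1:
            tp += 1
        elif y_true == 0 and y_pred == 1:
            fp += 1
        elif y_true == 1 and y_pred == 0:
            fn += 1
        else:
            tn += 1
    return EvalReport(tp=tp, fp=fp, fn=fn, tn=tn, **report_fields)


def _fit_predict(
    model_name: str,
    train_spans: list[str],
    train_labels: list[int],
    test_spans: list[str],
    seed: int,
    val_spans: list[str] | None = None,
    val_labels: list[int] | None = None,
    model_kwargs: dict | None = None,
) -> np.ndarray:
    kwargs = dict(model_kwargs or {})
    kwargs.setdefault("train_config", TrainConfig(seed=seed))
    model = get_model(model_name, **kwargs)
    model.fit(train_spans, train_labels, val_spans, val_labels)
    return model.predict_scores(test_spans)


def run_intra(
    dataset: RelationDataset,
    model_name: str,
    protocol: str = "intra_cv",
    split: Sequence[str] | None = None,
    n_splits: int = 5,
    seed: int = DEFAULT_SEED,
    model_kwargs: dict | None = None,
    return_predictions: bool = False,
):
    """Intra-corpus evaluation.

    ``intra_cv``: stratified ``n_splits``-fold CV, confusion counts pooled
    over folds (every candidate is tested exactly once).  ``intra_fixed``:
    honor a provided per-candidate split assignment ("train"/"test").
    """
    if protocol not in ("intra_cv", "intra_fixed"):
        raise ValueError(f"unknown intra protocol {protocol!r}")
    spans = dataset.spans()
    labels = np.asarray(dataset.labels())
    ids = [c.candidate_id for c in dataset.candidates]
    predictions: list[Prediction] = []

    if protocol == "intra_cv":
        if min(np.bincount(labels, minlength=2)) < n_splits:
            raise ValueError(
                f"cannot stratify {n_splits} folds: minority class too small"
            )
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for train_idx, test_idx in skf.split(spans, labels):
            scores_fold = _fit_predict(
                model_name,
                [spans[i] for i in train_idx],
                labels[train_idx].tolist(),
                [spans[i] for i in test_idx],
                seed=seed,
                model_kwargs=model_kwargs,
            )
            predictions.extend(
                predictions_from_scores([ids[i] for i in test_idx], scores_fold)
            )
        gold = dict(zip(ids, labels.tolist()))
    else:
        if split is None:
            raise ValueError("intra_fixed requires a split assignment")
        split = list(split)
        if len(split) != len(ids):
            raise ValueError("split length does not match dataset")
        tr = [i for i, s in enumerate(split) if s == "train"]
        te = [i for i, s in enumerate(split) if s == "test"]
        if not te:
            raise ValueError("fixed split contains no test rows")
        scores_fixed = _fit_predict(
            model_name,
            [spans[i] for i in tr],
            labels[tr].tolist(),
            [spans[i] for i in te],
            seed=seed,
            model_kwargs=model_kwargs,
        )
        predictions = predictions_from_scores([ids[i] for i in te], scores_fixed)
        gold = {ids[i]: int(labels[i]) for i in te}

    report = score(
        predictions,
        gold,
        model_id=model_name,
        train_corpus=dataset.source_corpus,
        test_corpus=dataset.source_corpus,
        protocol=protocol,
        seed=seed,
    )
    return (report, predictions) if return_predictions else report


def run_inter(
    train_dataset: RelationDataset,
    test_dataset: RelationDataset,
    model_name: str,
    seed: int = DEFAULT_SEED,
    model_kwargs: dict | None = None,
    return_predictions: bool = False,
):
    """Train on one corpus, evaluate once on the full other corpus.

    30% of the training corpus is withheld (stratified, seeded) as the
    internal validation set used for model selection / early stopping.
    Overlapping dedup keys between the corpora trigger a leakage warning.
    """
    if len(test_dataset) == 0:
        raise ValueError("empty test dataset")
    overlap = {c.dedup_key for c in train_dataset} & {c.dedup_key for c in test_dataset}
    if overlap:
        warnings.warn(
            f"{len(overlap)} dedup key(s) shared between train and test corpora",
            stacklevel=2,
        )
    spans = train_dataset.spans()
    labels = train_dataset.labels()
    tr_spans, va_spans, tr_y, va_y = train_test_split(
        spans, labels, test_size=0.3, stratify=labels, random_state=seed
    )
    test_spans = test_dataset.spans()
    ids = [c.candidate_id for c in test_dataset.candidates]
    scores_test = _fit_predict(
        model_name,
        tr_spans,
        tr_y,
        test_spans,
        seed=seed,
        val_spans=va_spans,
        val_labels=va_y,
        model_kwargs=model_kwargs,
    )
    predictions = predictions_from_scores(ids, scores_test)
    gold = dict(zip(ids, test_dataset.labels()))
    report = score(
        predictions,
        gold,
        model_id=model_name,
        train_corpus=train_dataset.source_corpus,
        test_corpus=test_dataset.source_corpus,
        protocol="inter",
        seed=seed,
    )
    return (report, predictions) if return_predictions else report


# ---------------------------------------------------------------------------
# inter-annotator agreement


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """(p_o - p_e) / (1 - p_e) with marginal-product expected agreement.

    When p_e = 1 (both annotators constant): 1.0 if the sequences are
    identical, else a ``ValueError``.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    if len(labels_a) == 0:
        raise ValueError("empty label sequences")
    a = list(labels_a)
    b = list(labels_b)
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    cats = set(a) | set(b)
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    if abs(1.0 - p_e) < 1e-12:
        if p_o == 1.0:
            return 1.0
        raise ValueError("expected agreement is 1 but sequences differ")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class IaaReport:
    kappa: float
    pairwise_f: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa {self.kappa} outside [-1, 1]")


def _entity_keys(corpus: Corpus) -> dict[str, set[tuple]]:
    out: dict[str, set[tuple]] = {}
    for doc in corpus.documents:
        for e in doc.entities:
            out.setdefault(e.label, set()).add((doc.doc_id, e.start, e.end, e.label))
    return out


def _relation_keys(corpus: Corpus) -> dict[str, set[tuple]]:
    out: dict[str, set[tuple]] = {}
    for doc in corpus.documents:
        ents = {e.entity_id: e for e in doc.entities}
        for r in doc.relations:
            e1, e2 = ents[r.arg1], ents[r.arg2]
            out.setdefault(r.rel_type, set()).add(
                (doc.doc_id, r.rel_type, e1.start, e1.end, e2.start, e2.end)
            )
    return out


def pairwise_f_agreement(corpus_a: Corpus, corpus_b: Corpus) -> dict[str, float]:
    """Per-type F between two annotation sets over the same documents.

    Entities match on exact (span, label); relations on exact typed
    argument spans.  Treating A as reference, F = 2|A∩B| / (|A| + |B|) —
    symmetric in the two sets by construction.  Values are fractions in
    [0, 1].
    """
    docs_a = {d.doc_id for d in corpus_a.documents}
    docs_b = {d.doc_id for d in corpus_b.documents}
    if docs_a != docs_b:
        raise ValueError(
            f"annotation sets cover different documents: {sorted(docs_a ^ docs_b)[:5]}"
        )
    result: dict[str, float] = {}
    for keys_fn in (_entity_keys, _relation_keys):
        ka, kb = keys_fn(corpus_a), keys_fn(corpus_b)
        for typ in sorted(set(ka) | set(kb)):
            sa, sb = ka.get(typ, set()), kb.get(typ, set())
            denom = len(sa) + len(sb)
            result[typ] = 2 * len(sa & sb) / denom if denom else 0.0
    return result


# ---------------------------------------------------------------------------
# per-sample model-agreement cluster maps


@dataclass
class AgreementMatrix:
    """Binary model x sample correctness matrix (1 = prediction matched gold)."""

    model_ids: list[str]
    candidate_ids: list[str]
    matrix: np.ndarray  # shape (n_models, n_samples), values in {0, 1}

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.model_ids), len(self.candidate_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix cells must be binary")

    @classmethod
    def from_predictions(
        cls,
        predictions_by_model: dict[str, Sequence[Prediction]],
        gold: dict[str, int],
        positive_class: bool | None = None,
    ) -> "AgreementMatrix":
        """Build the correctness matrix; optionally restrict to one class."""
        cids = sorted(
            cid
            for cid, y in gold.items()
            if positive_class is None or y == int(positive_class)
        )
        rows = []
        model_ids = sorted(predictions_by_model)
        for mid in model_ids:
            by_id = {p.candidate_id: p for p in predictions_by_model[mid]}
            rows.append([int(by_id[c].y == gold[c]) for c in cids])
        return cls(model_ids=model_ids, candidate_ids=cids, matrix=np.array(rows))


def agreement_cluster_map(
    matrix: AgreementMatrix,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Hierarchically cluster model rows (Hamming distance, average linkage).

    Returns (row order as model ids, linkage tree, reordered binary matrix).
    """
    if len(matrix.model_ids) < 2:
        raise ValueError("need at least two models to cluster")
    if len(matrix.candidate_ids) < 2:
        warnings.warn("single sample: clustering is degenerate", stacklevel=2)
    dist = pdist(matrix.matrix, metric="hamming")
    tree = linkage(dist, method="average")
    order = leaves_list(tree)
    ordered_ids = [matrix.model_ids[i] for i in order]
    return ordered_ids, tree, matrix.matrix[order]


def render_cluster_map(
    matrix: AgreementMatrix, out_path: str | Path, title: str = ""
) -> Path:
    """Render the ordered correctness matrix to an image; also writes the
    machine-readable row order next to it."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered_ids, _, ordered = agreement_cluster_map(matrix)
    fig, ax = plt.subplots(figsize=(10, 2 + 0.4 * len(ordered_ids)))
    ax.imshow(ordered, aspect="auto", cmap="cividis", interpolation="nearest")
    ax.set_yticks(range(len(ordered_ids)), ordered_ids)
    ax.set_xlabel("samples")
    if title:
        ax.set_title(title)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    out_path.with_suffix(".order.json").write_text(
        json.dumps({"row_order": ordered_ids}), encoding="utf-8"
    )
    return out_path
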