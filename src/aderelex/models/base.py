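"""Shared model-layer plumbing: configs, tokenizer, predictions, registry."""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "TrainConfig",
    "NgramConfig",
    "Prediction",
    "RelationClassifier",
    "tokenize",
    "register_model",
    "get_model",
    "available_models",
    "UntrainedModelError",
    "DegenerateDataError",
]

LEARNING_RATES = (0.1, 0.01, 0.001, 0.0001)
BATCH_SIZES = (16, 32, 64)
DECISION_THRESHOLD = 0.5


class UntrainedModelError(RuntimeError):
    """predict() called before fit()."""


class DegenerateDataError(ValueError):
    """Training data contains a single class."""


@dataclass(frozen=True)
class TrainConfig:
    """Neural-training knobs restricted to the searched value sets."""

    dropout: float = 0.5
    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 20
    seed: int = 0
    patience: int = 3  # early stopping on validation F1

    def __post_init__(self) -> None:
        if not 0.1 <= self.dropout <= 0.8:
            raise ValueError(f"dropout {self.dropout} outside [0.1, 0.8]")
        if self.learning_rate not in LEARNING_RATES:
            raise ValueError(f"learning_rate must be one of {LEARNING_RATES}")
        if self.batch_size not in BATCH_SIZES:
            raise ValueError(f"batch_size must be one of {BATCH_SIZES}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class NgramConfig:
    n_min: int = 2
    n_max: int = 5
    level: str = "character"

    def __post_init__(self) -> None:
        if not 1 <= self.n_min <= self.n_max <= 8:
            raise ValueError("require 1 <= n_min <= n_max <= 8")
        if self.level not in ("character", "token"):
            raise ValueError("level must be 'character' or 'token'")


@dataclass(frozen=True)
class Prediction:
    candidate_id: str
    y: int
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.y != int(self.score >= DECISION_THRESHOLD):
            raise ValueError("y must equal (score >= threshold)")


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase; split on whitespace and punctuation.

    Hyphenated compounds split into their parts ("nivolumab-induced" ->
    ["nivolumab", "induced"]).
    """
    return _TOKEN_RE.findall(text.lower())


class RelationClassifier(Protocol):
    """Contract every registered model (in-tree or external adapter) meets."""

    def fit(
        self,
        spans: Sequence[str],
        labels: Sequence[int],
        val_spans: Sequence[str] | None = None,
        val_labels: Sequence[int] | None = None,
    ) -> "RelationClassifier": ...

    def predict_scores(self, spans: Sequence[str]) -> np.ndarray: ...


_REGISTRY: dict[str, type] = {}


def register_model(name: str, cls: type | None = None):
    """Register a classifier class under ``name`` (usable as decorator)."""
    def _inner(c):
        _REGISTRY[name] = c
        return c

    return _inner(cls) if cls is not None else _inner


def get_model(name: str, **kwargs) -> RelationClassifier:
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
    return cls(**kwargs)


def available_models() -> list[str]:
    return sorted(_REGISTRY)


def predictions_from_scores(
    candidate_ids: Sequence[str], scores: np.ndarray
) -> list[Prediction]:
    """Pair ids with scores and apply the 0.5 decision threshold."""
    return [
        Prediction(candidate_id=cid, y=int(s >= DECISION_THRESHOLD), score=float(s))
        for cid, s in zip(candidate_ids, scores, strict=True)
    ]


def check_two_classes(labels: Sequence[int]) -> None:
    if len(set(labels)) < 2:
        raise DegenerateDataError("training data contains a single class")


def f1_positive(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Positive-class F1 used for model selection (0 when undefined)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0
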