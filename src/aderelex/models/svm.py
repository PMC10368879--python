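"""Maximum-margin classifier over character n-gram TF-IDF features.

RBF kernel; (c, gamma) chosen by grid search maximizing positive-class F1
on an internal stratified validation split, then refit on the full
training portion.  Scores are a logistic squashing of the signed margin,
so score >= 0.5 iff the margin is non-negative.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .base import (
    NgramConfig,
    TrainConfig,
    UntrainedModelError,
    check_two_classes,
    f1_positive,
    register_model,
)
from .tfidf import CharNgramTfidf

__all__ = ["SvmConfig", "SvmRelationClassifier"]

DEFAULT_C_GRID = (0.1, 1.0, 10.0)
DEFAULT_GAMMA_GRID = ("scale", 0.1, 1.0)


@dataclass
class SvmConfig:
    c: float = 1.0
    gamma: float | str = "scale"
    ngram: NgramConfig = field(default_factory=NgramConfig)
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")


@register_model("svm")
class SvmRelationClassifier:
    def __init__(
        self,
        config: SvmConfig | None = None,
        train_config: TrainConfig | None = None,
        grid_search: bool = True,
        class_weight: str | None = None,  # "balanced" enables inverse-prevalence weighting
    ):
        self.config = config or SvmConfig()
        self.train_config = train_config or TrainConfig()
        self.grid_search = grid_search
        self.class_weight = class_weight
        self.vectorizer = CharNgramTfidf(self.config.ngram)
        self._clf: SVC | None = None
        self.best_params_: dict | None = None

    def _new_clf(self, c: float, gamma) -> SVC:
        return SVC(
            C=c,
            gamma=gamma,
            kernel="rbf",
            class_weight=self.class_weight,
            random_state=self.train_config.seed,
        )

    def fit(
        self,
        spans: Sequence[str],
        labels: Sequence[int],
        val_spans: Sequence[str] | None = None,
        val_labels: Sequence[int] | None = None,
    ) -> "SvmRelationClassifier":
        check_two_classes(labels)
        y = np.asarray(labels, dtype=int)

        if self.grid_search:
            if val_spans is None:
                tr_spans, va_spans, tr_y, va_y = train_test_split(
                    list(spans),
                    y,
                    test_size=0.3,
                    stratify=y,
                    random_state=self.train_config.seed,
                )
            else:
                tr_spans, tr_y = list(spans), y
                va_spans, va_y = list(val_spans), np.asarray(val_labels, dtype=int)
            sel_vec = CharNgramTfidf(self.config.ngram).fit(tr_spans)
            x_tr = sel_vec.transform(tr_spans)
            x_va = sel_vec.transform(va_spans)
            best = (-1.0, self.config.c, self.config.gamma)
            for c in self.config.c_grid:
                for gamma in self.config.gamma_grid:
                    clf = self._new_clf(c, gamma).fit(x_tr, tr_y)
                    f1 = f1_positive(va_y, clf.predict(x_va))
                    if f1 > best[0]:
                        best = (f1, c, gamma)
            _, self.config.c, self.config.gamma = best
            self.best_params_ = {"c": self.config.c, "gamma": self.config.gamma}

        # refit vectorizer + model on the full training portion
        x = self.vectorizer.fit(list(spans)).transform(list(spans))
        self._clf = self._new_clf(self.config.c, self.config.gamma).fit(x, y)
        return self

    def predict_scores(self, spans: Sequence[str]) -> np.ndarray:
        if self._clf is None:
            raise UntrainedModelError("model not trained")
        margins = self._clf.decision_function(self.vectorizer.transform(list(spans)))
        return 1.0 / (1.0 + np.exp(-margins))
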