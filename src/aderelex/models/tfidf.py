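"""Character n-gram TF-IDF vectorization.

The variant is fixed and documented: raw term counts, smoothed idf
``ln((1 + N) / (1 + df)) + 1``, and L2-normalized rows.  Backed by
scikit-learn's ``TfidfVectorizer`` (which implements exactly this variant
with ``smooth_idf=True, norm='l2'``); the unit tests pin the hand-computed
values so a drift in the backend would be caught.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from .base import NgramConfig, UntrainedModelError

__all__ = ["CharNgramTfidf"]


class CharNgramTfidf:
    """Fit-on-train-only character (or token) n-gram TF-IDF vectorizer."""

    def __init__(self, config: NgramConfig | None = None):
        self.config = config or NgramConfig()
        self._vec: TfidfVectorizer | None = None

    def fit(self, corpus_spans: Sequence[str]) -> "CharNgramTfidf":
        if len(corpus_spans) == 0:
            raise ValueError("cannot fit on an empty span list")
        longest = max(len(s) for s in corpus_spans)
        if self.config.level == "character" and self.config.n_max > longest:
            warnings.warn(
                f"n_max={self.config.n_max} exceeds longest span ({longest} chars); "
                "vocabulary will contain shorter grams only",
                stacklevel=2,
            )
        analyzer = "char" if self.config.level == "character" else "word"
        self._vec = TfidfVectorizer(
            analyzer=analyzer,
            ngram_range=(self.config.n_min, self.config.n_max),
            lowercase=True,
            norm="l2",
            smooth_idf=True,
            sublinear_tf=False,
        )
        # tolerate spans shorter than n_min (vectorizer raises on empty vocab)
        try:
            self._vec.fit(corpus_spans)
        except ValueError as exc:
            raise ValueError(f"no n-grams could be extracted: {exc}") from exc
        return self

    def transform(self, spans: Sequence[str]) -> sp.csr_matrix:
        """Rows are L2-unit or all-zero; only fitted vocabulary is used."""
        if self._vec is None:
            raise UntrainedModelError("vectorizer not fitted")
        return self._vec.transform(spans)

    def fit_transform(self, spans: Sequence[str]) -> sp.csr_matrix:
        self.fit(spans)
        return self.transform(spans)

    @property
    def vocabulary(self) -> dict[str, int]:
        if self._vec is None:
            raise UntrainedModelError("vectorizer not fitted")
        return dict(self._vec.vocabulary_)

    def idf(self) -> np.ndarray:
        if self._vec is None:
            raise UntrainedModelError("vectorizer not fitted")
        return self._vec.idf_.copy()
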