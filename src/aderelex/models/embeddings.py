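"""Word-vector tables in the whitespace-delimited text format.

Each line is ``token v1 v2 ... vD``; all lines must share one dimension D.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["EmbeddingTable", "load_embeddings", "EmbeddingFormatError"]


class EmbeddingFormatError(ValueError):
    """Ragged or unparseable embedding file; message names the line."""


class EmbeddingTable:
    """token -> fixed-dimension vector with a configurable OOV policy.

    ``oov_policy`` is ``"zero"`` (default) or ``"random"`` (seeded normal,
    one draw per unseen token, cached so lookups are stable).
    """

    def __init__(
        self,
        vectors: dict[str, np.ndarray],
        oov_policy: str = "zero",
        seed: int = 0,
        case_fold: bool = True,
    ):
        if not vectors:
            raise ValueError("empty embedding table")
        dims = {v.shape for v in vectors.values()}
        if len(dims) != 1:
            raise EmbeddingFormatError(f"inconsistent vector shapes: {dims}")
        if oov_policy not in ("zero", "random"):
            raise ValueError("oov_policy must be 'zero' or 'random'")
        self.case_fold = case_fold
        self._vectors = (
            {k.casefold(): v for k, v in vectors.items()} if case_fold else dict(vectors)
        )
        self.dim = next(iter(vectors.values())).shape[0]
        self.oov_policy = oov_policy
        self._rng = np.random.default_rng(seed)
        self._oov_cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, token: str) -> bool:
        return (token.casefold() if self.case_fold else token) in self._vectors

    def lookup(self, token: str) -> np.ndarray:
        key = token.casefold() if self.case_fold else token
        if key in self._vectors:
            return self._vectors[key]
        if self.oov_policy == "zero":
            return np.zeros(self.dim)
        if key not in self._oov_cache:
            self._oov_cache[key] = self._rng.normal(0.0, 0.1, self.dim)
        return self._oov_cache[key]

    def matrix_for(self, tokens: list[str]) -> np.ndarray:
        """Stack lookups into a (len(tokens), dim) array."""
        return np.vstack([self.lookup(t) for t in tokens]) if tokens else np.zeros((0, self.dim))


def load_embeddings(
    path: str | Path,
    oov_policy: str = "zero",
    seed: int = 0,
    case_fold: bool = True,
) -> EmbeddingTable:
    """Parse a text word-vector file; raises on ragged dimensions."""
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip().split(" ")
        if len(parts) < 2:
            raise EmbeddingFormatError(f"line {lineno}: no vector components")
        token = parts[0]
        try:
            vec = np.array([float(x) for x in parts[1:]])
        except ValueError:
            raise EmbeddingFormatError(
                f"line {lineno}: non-numeric vector component"
            ) from None
        if dim is None:
            dim = vec.shape[0]
        elif vec.shape[0] != dim:
            raise EmbeddingFormatError(
                f"line {lineno}: dimension {vec.shape[0]} != expected {dim}"
            )
        vectors[token] = vec
    if not vectors:
        raise EmbeddingFormatError("file contains no vectors")
    return EmbeddingTable(vectors, oov_policy=oov_policy, seed=seed, case_fold=case_fold)
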