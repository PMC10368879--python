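"""Token-level neural classifiers implemented in NumPy.

Both the convolutional and the bidirectional-recurrent model share the
same skeleton: tokenizer -> index -> embedding (trained or pretrained) ->
encoder -> dropout -> dense sigmoid head, trained with mini-batch Adam on
binary cross-entropy, early-stopped on validation positive-class F1.

All randomness (initialization, shuffling, dropout) flows from a single
``numpy`` generator seeded by ``TrainConfig.seed``, so training is
bit-reproducible given the same dataset order.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .base import (
    TrainConfig,
    UntrainedModelError,
    check_two_classes,
    f1_positive,
    register_model,
    tokenize,
)
from .embeddings import EmbeddingTable

__all__ = [
    "CnnSpec",
    "BilstmSpec",
    "CnnRelationClassifier",
    "BilstmRelationClassifier",
    "Vocabulary",
]

PAD, UNK = 0, 1


class Vocabulary:
    """Token index built from training spans only (ids 0/1 = pad/unk)."""

    def __init__(self, spans: Sequence[str]):
        tokens = sorted({t for s in spans for t in tokenize(s)})
        self.index = {t: i + 2 for i, t in enumerate(tokens)}
        self.tokens = ["<pad>", "<unk>"] + tokens

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(
        self, spans: Sequence[str], max_len: int, reverse: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pad/truncate to ``max_len``; returns (ids B x S, lengths B)."""
        ids = np.full((len(spans), max_len), PAD, dtype=np.int64)
        lengths = np.zeros(len(spans), dtype=np.int64)
        for i, span in enumerate(spans):
            toks = tokenize(span)[:max_len]
            if reverse:
                toks = toks[::-1]
            lengths[i] = max(1, len(toks))
            for j, t in enumerate(toks):
                ids[i, j] = self.index.get(t, UNK)
        return ids, lengths


@dataclass(frozen=True)
class CnnSpec:
    max_tokens: int = 40                      # S_n
    embedding_dim: int = 50                   # S_d (300 when pretrained vectors used)
    kernel_sizes: tuple[int, ...] = (2, 3, 4)  # W_h
    n_filters: int = 16
    freeze_embeddings: bool = False

    def __post_init__(self) -> None:
        if self.max_tokens < 2:
            raise ValueError("max_tokens must be >= 2")
        if any(h > self.max_tokens for h in self.kernel_sizes):
            raise ValueError("kernel size exceeds max_tokens")


@dataclass(frozen=True)
class BilstmSpec:
    max_tokens: int = 40
    embedding_dim: int = 50
    hidden_units: int = 16
    freeze_embeddings: bool = False

    def __post_init__(self) -> None:
        if self.max_tokens < 2:
            raise ValueError("max_tokens must be >= 2")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _init_embedding(
    vocab: Vocabulary,
    dim: int,
    table: EmbeddingTable | None,
    rng: np.random.Generator,
) -> np.ndarray:
    if table is not None:
        emb = np.vstack([table.lookup(t) for t in vocab.tokens])
        emb[PAD] = 0.0
        return emb
    emb = rng.normal(0.0, 0.1, (len(vocab), dim))
    emb[PAD] = 0.0
    return emb


class _NeuralBase:
    """Shared fit loop: batching, Adam, dropout, early stopping."""

    train_config: TrainConfig

    def __init__(
        self,
        train_config: TrainConfig | None = None,
        embedding_table: EmbeddingTable | None = None,
    ):
        self.train_config = train_config or TrainConfig()
        self.embedding_table = embedding_table
        self.vocab: Vocabulary | None = None
        self.params: dict[str, np.ndarray] | None = None
        self._rng = np.random.default_rng(self.train_config.seed)

    # subclass API ---------------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def _encode(self, spans: Sequence[str]):
        raise NotImplementedError

    def _forward(self, enc, train: bool, rng) -> tuple[np.ndarray, dict]:
        raise NotImplementedError

    def _backward(self, cache: dict, dlogit: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError

    # ----------------------------------------------------------------------
    def fit(
        self,
        spans: Sequence[str],
        labels: Sequence[int],
        val_spans: Sequence[str] | None = None,
        val_labels: Sequence[int] | None = None,
    ):
        check_two_classes(labels)
        cfg = self.train_config
        self._rng = np.random.default_rng(cfg.seed)
        if self.embedding_table is not None:
            # pretrained vectors fix the embedding width
            self.spec = self._spec_with_dim(self.embedding_table.dim)
        self.vocab = Vocabulary(spans)
        self.params = self._init_params(self._rng)
        optimizer = _Adam(self.params, cfg.learning_rate)

        y = np.asarray(labels, dtype=float)
        enc_all = self._encode(spans)
        n = len(y)
        has_val = val_spans is not None and len(val_spans) > 0
        if has_val:
            enc_val = self._encode(val_spans)
            y_val = np.asarray(val_labels, dtype=int)
        best_f1, best_params, patience_left = -1.0, None, cfg.patience

        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                enc_b = tuple(a[idx] for a in enc_all)
                probs, cache = self._forward(enc_b, train=True, rng=self._rng)
                dlogit = (probs - y[idx]) / len(idx)
                grads = self._backward(cache, dlogit)
                optimizer.step(self.params, grads)
            if has_val:
                p_val, _ = self._forward(enc_val, train=False, rng=self._rng)
                f1 = f1_positive(y_val, (p_val >= 0.5).astype(int))
                if f1 > best_f1 + 1e-12:
                    best_f1, patience_left = f1, cfg.patience
                    best_params = {k: v.copy() for k, v in self.params.items()}
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if has_val and best_params is not None:
            self.params = best_params
        return self

    def predict_scores(self, spans: Sequence[str]) -> np.ndarray:
        if self.params is None or self.vocab is None:
            raise UntrainedModelError("model not trained")
        if len(spans) == 0:
            return np.zeros(0)
        probs, _ = self._forward(self._encode(spans), train=False, rng=self._rng)
        return probs

    def _dropout(self, x: np.ndarray, train: bool, rng) -> tuple[np.ndarray, np.ndarray | None]:
        if not train:
            return x, None
        keep = 1.0 - self.train_config.dropout
        mask = (rng.random(x.shape) < keep) / keep
        return x * mask, mask


@register_model("cnn")
class CnnRelationClassifier(_NeuralBase):
    """Parallel convolutions of sizes W_h -> ReLU -> max-over-time -> dense."""

    def __init__(
        self,
        spec: CnnSpec | None = None,
        train_config: TrainConfig | None = None,
        embedding_table: EmbeddingTable | None = None,
    ):
        super().__init__(train_config, embedding_table)
        self.spec = spec or CnnSpec()

    def _spec_with_dim(self, dim: int) -> CnnSpec:
        return CnnSpec(
            max_tokens=self.spec.max_tokens,
            embedding_dim=dim,
            kernel_sizes=self.spec.kernel_sizes,
            n_filters=self.spec.n_filters,
            freeze_embeddings=self.spec.freeze_embeddings,
        )

    def _init_params(self, rng) -> dict[str, np.ndarray]:
        d, nf = self.spec.embedding_dim, self.spec.n_filters
        params = {"E": _init_embedding(self.vocab, d, self.embedding_table, rng)}
        for h in self.spec.kernel_sizes:
            fan_in = h * d
            params[f"W{h}"] = rng.normal(0.0, 1.0 / np.sqrt(fan_in), (nf, fan_in))
            params[f"b{h}"] = np.zeros(nf)
        total = nf * len(self.spec.kernel_sizes)
        params["dense_w"] = rng.normal(0.0, 1.0 / np.sqrt(total), total)
        params["dense_b"] = np.zeros(1)
        return params

    def _encode(self, spans):
        ids, _ = self.vocab.encode(spans, self.spec.max_tokens)
        return (ids,)

    def _forward(self, enc, train: bool, rng):
        (ids,) = enc
        p = self.params
        emb = p["E"][ids]  # B x S x d
        B, S, d = emb.shape
        pooled_parts, cache_h = [], {}
        for h in self.spec.kernel_sizes:
            T = S - h + 1
            win = np.lib.stride_tricks.sliding_window_view(emb, (h, d), axis=(1, 2))
            win = win.reshape(B, T, h * d)
            z = win @ p[f"W{h}"].T + p[f"b{h}"]  # B x T x F
            a = np.maximum(z, 0.0)
            arg = a.argmax(axis=1)  # B x F
            pooled = np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :]
            pooled_parts.append(pooled)
            cache_h[h] = (win, z, arg)
        feat = np.concatenate(pooled_parts, axis=1)
        feat_d, mask = self._dropout(feat, train, rng)
        logit = feat_d @ p["dense_w"] + p["dense_b"][0]
        probs = _sigmoid(logit)
        cache = {"ids": ids, "cache_h": cache_h, "feat_d": feat_d, "mask": mask, "B": B}
        return probs, cache

    def _backward(self, cache, dlogit):
        p = self.params
        nf = self.spec.n_filters
        grads = {
            "dense_w": cache["feat_d"].T @ dlogit,
            "dense_b": np.array([dlogit.sum()]),
        }
        dfeat = np.outer(dlogit, p["dense_w"])
        if cache["mask"] is not None:
            dfeat = dfeat * cache["mask"]
        ids = cache["ids"]
        B, S = ids.shape
        d = self.spec.embedding_dim
        demb = np.zeros((B, S, d))
        for k, h in enumerate(self.spec.kernel_sizes):
            win, z, arg = cache["cache_h"][h]
            dpool = dfeat[:, k * nf : (k + 1) * nf]  # B x F
            da = np.zeros_like(z)
            np.put_along_axis(da, arg[:, None, :], dpool[:, None, :], axis=1)
            dz = da * (z > 0)
            grads[f"W{h}"] = np.einsum("btf,btk->fk", dz, win)
            grads[f"b{h}"] = dz.sum(axis=(0, 1))
            dwin = np.einsum("btf,fk->btk", dz, p[f"W{h}"])
            T = S - h + 1
            dwin = dwin.reshape(B, T, h, d)
            for j in range(h):
                demb[:, j : j + T, :] += dwin[:, :, j, :]
        if not self.spec.freeze_embeddings:
            dE = np.zeros_like(p["E"])
            np.add.at(dE, ids, demb)
            dE[PAD] = 0.0
            grads["E"] = dE
        return grads


def _lstm_forward(x, mask, Wx, Wh, b):
    """x: B x S x d, mask: B x S (1 where token valid). Returns h_last, caches."""
    B, S, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    caches = []
    for t in range(S):
        m = mask[:, t : t + 1]
        xt = x[:, t, :]
        pre = xt @ Wx + h @ Wh + b
        i = _sigmoid(pre[:, :H])
        f = _sigmoid(pre[:, H : 2 * H])
        g = np.tanh(pre[:, 2 * H : 3 * H])
        o = _sigmoid(pre[:, 3 * H :])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        caches.append((xt, h, c, i, f, g, o, c_new, m))
        c = m * c_new + (1 - m) * c
        h = m * h_new + (1 - m) * h
    return h, caches


def _lstm_backward(dh_last, caches, Wx, Wh):
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh = dh_last
    dc = np.zeros_like(dh_last)
    dx_steps = []
    for xt, h_prev, c_prev, i, f, g, o, c_new, m in reversed(caches):
        dh_new = dh * m
        dh_carry = dh * (1 - m)
        dc_new = dc * m
        dc_carry = dc * (1 - m)
        tanh_c = np.tanh(c_new)
        do = dh_new * tanh_c
        dc_total = dc_new + dh_new * o * (1 - tanh_c**2)
        df = dc_total * c_prev
        di = dc_total * g
        dg = dc_total * i
        dc_prev = dc_total * f
        dpre = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        dWx += xt.T @ dpre
        dWh += h_prev.T @ dpre
        db += dpre.sum(axis=0)
        dx_steps.append(dpre @ Wx.T)
        dh = dh_carry + dpre @ Wh.T
        dc = dc_carry + dc_prev
    dx = np.stack(dx_steps[::-1], axis=1)  # B x S x d
    return dWx, dWh, db, dx


@register_model("bilstm")
class BilstmRelationClassifier(_NeuralBase):
    """Bidirectional recurrent encoder; head on concatenated terminal states."""

    def __init__(
        self,
        spec: BilstmSpec | None = None,
        train_config: TrainConfig | None = None,
        embedding_table: EmbeddingTable | None = None,
    ):
        super().__init__(train_config, embedding_table)
        self.spec = spec or BilstmSpec()

    def _spec_with_dim(self, dim: int) -> BilstmSpec:
        return BilstmSpec(
            max_tokens=self.spec.max_tokens,
            embedding_dim=dim,
            hidden_units=self.spec.hidden_units,
            freeze_embeddings=self.spec.freeze_embeddings,
        )

    def _init_params(self, rng) -> dict[str, np.ndarray]:
        d, H = self.spec.embedding_dim, self.spec.hidden_units
        params = {"E": _init_embedding(self.vocab, d, self.embedding_table, rng)}
        for direction in ("f", "b"):
            params[f"Wx_{direction}"] = rng.normal(0.0, 1.0 / np.sqrt(d), (d, 4 * H))
            params[f"Wh_{direction}"] = rng.normal(0.0, 1.0 / np.sqrt(H), (H, 4 * H))
            bias = np.zeros(4 * H)
            bias[H : 2 * H] = 1.0  # forget-gate bias
            params[f"b_{direction}"] = bias
        params["dense_w"] = rng.normal(0.0, 1.0 / np.sqrt(2 * H), 2 * H)
        params["dense_b"] = np.zeros(1)
        return params

    def _encode(self, spans):
        fwd, lengths = self.vocab.encode(spans, self.spec.max_tokens)
        bwd, _ = self.vocab.encode(spans, self.spec.max_tokens, reverse=True)
        return fwd, bwd, lengths

    def _forward(self, enc, train: bool, rng):
        fwd, bwd, lengths = enc
        p = self.params
        S = fwd.shape[1]
        mask = (np.arange(S)[None, :] < lengths[:, None]).astype(float)
        emb_f = p["E"][fwd]
        emb_b = p["E"][bwd]
        h_f, caches_f = _lstm_forward(emb_f, mask, p["Wx_f"], p["Wh_f"], p["b_f"])
        h_b, caches_b = _lstm_forward(emb_b, mask, p["Wx_b"], p["Wh_b"], p["b_b"])
        feat = np.concatenate([h_f, h_b], axis=1)
        feat_d, drop_mask = self._dropout(feat, train, rng)
        logit = feat_d @ p["dense_w"] + p["dense_b"][0]
        probs = _sigmoid(logit)
        cache = {
            "fwd": fwd,
            "bwd": bwd,
            "caches_f": caches_f,
            "caches_b": caches_b,
            "feat_d": feat_d,
            "drop_mask": drop_mask,
        }
        return probs, cache

    def _backward(self, cache, dlogit):
        p = self.params
        H = self.spec.hidden_units
        grads = {
            "dense_w": cache["feat_d"].T @ dlogit,
            "dense_b": np.array([dlogit.sum()]),
        }
        dfeat = np.outer(dlogit, p["dense_w"])
        if cache["drop_mask"] is not None:
            dfeat = dfeat * cache["drop_mask"]
        dWx_f, dWh_f, db_f, dx_f = _lstm_backward(
            dfeat[:, :H], cache["caches_f"], p["Wx_f"], p["Wh_f"]
        )
        dWx_b, dWh_b, db_b, dx_b = _lstm_backward(
            dfeat[:, H:], cache["caches_b"], p["Wx_b"], p["Wh_b"]
        )
        grads.update(
            Wx_f=dWx_f, Wh_f=dWh_f, b_f=db_f, Wx_b=dWx_b, Wh_b=dWh_b, b_b=db_b
        )
        if not self.spec.freeze_embeddings:
            dE = np.zeros_like(p["E"])
            np.add.at(dE, cache["fwd"], dx_f)
            np.add.at(dE, cache["bwd"], dx_b)
            dE[PAD] = 0.0
            grads["E"] = dE
        return grads
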