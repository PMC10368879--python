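import math

import numpy as np
import pytest

from aderelex.models import (
    BilstmRelationClassifier,
    BilstmSpec,
    CharNgramTfidf,
    CnnRelationClassifier,
    CnnSpec,
    DegenerateDataError,
    EmbeddingFormatError,
    EmbeddingTable,
    NgramConfig,
    Prediction,
    SvmRelationClassifier,
    TrainConfig,
    UntrainedModelError,
    available_models,
    get_model,
    load_embeddings,
    predictions_from_scores,
    tokenize,
)
from aderelex.models.nn import Vocabulary


class TestConfigs:
    def test_ngram_bounds(self):
        with pytest.raises(ValueError):
            NgramConfig(n_min=0)
        with pytest.raises(ValueError):
            NgramConfig(n_min=3, n_max=2)
        with pytest.raises(ValueError):
            NgramConfig(n_max=9)

    @pytest.mark.parametrize("kwargs", [
        {"dropout": 0.05},
        {"dropout": 0.9},
        {"learning_rate": 0.02},
        {"batch_size": 7},
        {"epochs": 0},
    ])
    def test_train_config_value_sets(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)

    def test_train_config_valid_values(self):
        for lr in (0.1, 0.01, 0.001, 0.0001):
            for bs in (16, 32, 64):
                TrainConfig(learning_rate=lr, batch_size=bs)

    def test_prediction_threshold_invariant(self):
        Prediction("c", 1, 0.5)
        Prediction("c", 0, 0.49)
        with pytest.raises(ValueError):
            Prediction("c", 0, 0.7)
        with pytest.raises(ValueError):
            Prediction("c", 1, 1.2)

    def test_cnn_spec_too_short(self):
        with pytest.raises(ValueError):
            CnnSpec(max_tokens=1)


class TestTokenizer:
    def test_hyphenated_drug_terms(self):
        assert tokenize("Nivolumab-induced rash!") == ["nivolumab", "induced", "rash"]

    def test_empty(self):
        assert tokenize("...") == []


class TestCharNgramTfidf:
    def test_hand_computed_two_document_example(self):
        # spans ["ab", "ab"], n=2: one gram, idf = ln((1+2)/(1+2)) + 1 = 1,
        # each row L2-normalizes to exactly [1.0]
        vec = CharNgramTfidf(NgramConfig(n_min=2, n_max=2)).fit(["ab", "ab"])
        assert set(vec.vocabulary) == {"ab"}
        assert vec.idf() == pytest.approx([1.0])
        x = vec.transform(["ab", "ab"]).toarray()
        assert x == pytest.approx(np.array([[1.0], [1.0]]))

    def test_idf_formula_on_unequal_dfs(self):
        # grams of ["ab","cd"]: df=1 each, idf = ln(3/2)+1
        vec = CharNgramTfidf(NgramConfig(n_min=2, n_max=2)).fit(["ab", "cd"])
        assert sorted(vec.idf()) == pytest.approx([math.log(3 / 2) + 1] * 2)

    def test_empty_string_transforms_to_zero_vector(self):
        vec = CharNgramTfidf(NgramConfig(n_min=2, n_max=2)).fit(["abcd"])
        assert vec.transform([""]).toarray() == pytest.approx(np.zeros((1, 3)))

    def test_rows_unit_norm_or_zero(self):
        spans = ["colitis due to nivolumab", "rash", "", "xy"]
        vec = CharNgramTfidf(NgramConfig(2, 4)).fit([s for s in spans if s])
        norms = np.sqrt((vec.transform(spans).toarray() ** 2).sum(axis=1))
        for n in norms:
            assert n == pytest.approx(1.0) or n == pytest.approx(0.0)

    def test_unseen_grams_ignored(self):
        vec = CharNgramTfidf(NgramConfig(2, 2)).fit(["ab"])
        assert vec.transform(["zz"]).toarray() == pytest.approx(np.array([[0.0]]))

    def test_n_max_longer_than_spans_warns(self):
        with pytest.warns(UserWarning, match="n_max"):
            CharNgramTfidf(NgramConfig(2, 8)).fit(["abc", "ab"])

    def test_untrained_raises(self):
        with pytest.raises(UntrainedModelError):
            CharNgramTfidf().transform(["x"])


def _perfect_signal_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    drugs = ["nivolumab", "keytruda", "avelumab"]
    ades = ["rash", "colitis", "hepatitis"]
    spans, labels = [], []
    for i in range(n):
        d, a = rng.choice(drugs), rng.choice(ades)
        if i % 2:
            spans.append(f"{a} attributed {d}")
            labels.append(1)
        else:
            spans.append(f"{a} monitored during {d}")
            labels.append(0)
    return spans, labels


class TestSvm:
    def test_perfect_signal_f1_one(self):
        spans, labels = _perfect_signal_data()
        test_spans, test_labels = _perfect_signal_data(n=30, seed=9)
        model = SvmRelationClassifier(train_config=TrainConfig(seed=0))
        model.fit(spans, labels)
        preds = (model.predict_scores(test_spans) >= 0.5).astype(int)
        assert (preds == np.array(test_labels)).all()

    def test_single_class_raises(self):
        with pytest.raises(DegenerateDataError):
            SvmRelationClassifier().fit(["a b", "c d"], [1, 1])

    def test_deterministic_given_seed(self):
        spans, labels = _perfect_signal_data()
        s1 = SvmRelationClassifier(train_config=TrainConfig(seed=3)).fit(spans, labels)
        s2 = SvmRelationClassifier(train_config=TrainConfig(seed=3)).fit(spans, labels)
        x = ["rash attributed nivolumab", "rash monitored during keytruda"]
        assert s1.predict_scores(x) == pytest.approx(s2.predict_scores(x))

    def test_score_threshold_matches_margin_sign(self):
        spans, labels = _perfect_signal_data()
        model = SvmRelationClassifier(train_config=TrainConfig(seed=0)).fit(spans, labels)
        scores = model.predict_scores(spans)
        margins = model._clf.decision_function(model.vectorizer.transform(spans))
        assert ((scores >= 0.5) == (margins >= 0)).all()

    def test_untrained_raises(self):
        with pytest.raises(UntrainedModelError):
            SvmRelationClassifier().predict_scores(["x"])

    def test_confident_duplicate_of_training_positive_scores_high(self):
        # moving a test span to equal a confidently-positive training span
        spans, labels = _perfect_signal_data()
        model = SvmRelationClassifier(train_config=TrainConfig(seed=0)).fit(spans, labels)
        pos_span = spans[labels.index(1)]
        ambiguous = "something unrelated entirely"
        assert model.predict_scores([pos_span])[0] >= model.predict_scores([ambiguous])[0]


class TestCnn:
    def test_pooled_feature_vector_length(self):
        # W_h = {2,3,4} with 8 filters each -> 24 pooled features
        model = CnnRelationClassifier(
            spec=CnnSpec(max_tokens=5, embedding_dim=4, n_filters=8),
            train_config=TrainConfig(seed=0, epochs=1),
        )
        model.vocab = Vocabulary(["a b c d e"])
        rng = np.random.default_rng(0)
        model.params = model._init_params(rng)
        enc = model._encode(["a b c d e"])
        _, cache = model._forward(enc, train=False, rng=rng)
        assert cache["feat_d"].shape == (1, 24)

    def test_perfect_signal_recovery(self):
        spans, labels = _perfect_signal_data(n=120)
        test_spans, test_labels = _perfect_signal_data(n=40, seed=5)
        model = CnnRelationClassifier(train_config=TrainConfig(seed=0, epochs=15))
        model.fit(spans, labels)
        preds = (model.predict_scores(test_spans) >= 0.5).astype(int)
        f1_denom = 2 * ((preds == 1) & (np.array(test_labels) == 1)).sum() + (
            (preds != np.array(test_labels)).sum()
        )
        assert (preds == np.array(test_labels)).mean() >= 0.95

    def test_zero_frozen_embedding_gives_constant_output(self):
        table = EmbeddingTable({"seen": np.zeros(4)}, oov_policy="zero")
        model = CnnRelationClassifier(
            spec=CnnSpec(max_tokens=5, embedding_dim=4, freeze_embeddings=True),
            train_config=TrainConfig(seed=0, epochs=1),
            embedding_table=table,
        )
        model.fit(["a b", "c d", "e f", "g h"], [0, 1, 0, 1])
        scores = model.predict_scores(["anything here", "totally different words"])
        assert scores[0] == pytest.approx(scores[1])

    def test_bit_reproducible_given_seed(self):
        spans, labels = _perfect_signal_data(n=40)
        cfg = TrainConfig(seed=11, epochs=3)
        m1 = CnnRelationClassifier(train_config=cfg).fit(spans, labels)
        m2 = CnnRelationClassifier(train_config=cfg).fit(spans, labels)
        x = ["rash attributed nivolumab"]
        assert m1.predict_scores(x) == pytest.approx(m2.predict_scores(x), abs=0)

    def test_gradients_match_finite_differences(self):
        model = CnnRelationClassifier(
            spec=CnnSpec(max_tokens=4, embedding_dim=3, kernel_sizes=(2,), n_filters=2),
            train_config=TrainConfig(seed=0),
        )
        _gradient_check(model, ["a b c", "c d", "b d a"], [1, 0, 1])


class TestBilstm:
    def test_single_token_deterministic(self):
        spans, labels = (["alpha", "beta"] * 10, [1, 0] * 10)
        cfg = TrainConfig(seed=2, epochs=2)
        m1 = BilstmRelationClassifier(train_config=cfg).fit(spans, labels)
        m2 = BilstmRelationClassifier(train_config=cfg).fit(spans, labels)
        assert m1.predict_scores(["alpha"]) == pytest.approx(m2.predict_scores(["alpha"]), abs=0)

    def test_perfect_signal_recovery(self):
        spans, labels = _perfect_signal_data(n=120)
        test_spans, test_labels = _perfect_signal_data(n=40, seed=5)
        model = BilstmRelationClassifier(train_config=TrainConfig(seed=0, epochs=15))
        model.fit(spans, labels)
        preds = (model.predict_scores(test_spans) >= 0.5).astype(int)
        assert (preds == np.array(test_labels)).mean() >= 0.95

    def test_direction_swap_symmetry_oracle(self):
        # reversing token order and swapping direction weights (and the dense
        # head halves) must reproduce the original outputs exactly
        spans = ["a b c d", "d c a", "b b a c"]
        model = BilstmRelationClassifier(
            spec=BilstmSpec(max_tokens=6, embedding_dim=3, hidden_units=2),
            train_config=TrainConfig(seed=4, epochs=1),
        )
        model.fit(spans + ["a", "b"], [1, 0, 1, 0, 1])
        base = model.predict_scores(spans)

        H = model.spec.hidden_units
        swapped = BilstmRelationClassifier(
            spec=model.spec, train_config=model.train_config
        )
        swapped.vocab = model.vocab
        p = {k: v.copy() for k, v in model.params.items()}
        for name in ("Wx", "Wh", "b"):
            p[f"{name}_f"], p[f"{name}_b"] = p[f"{name}_b"], p[f"{name}_f"]
        dense = p["dense_w"].copy()
        p["dense_w"] = np.concatenate([dense[H:], dense[:H]])
        swapped.params = p

        reversed_spans = [" ".join(s.split()[::-1]) for s in spans]
        assert swapped.predict_scores(reversed_spans) == pytest.approx(base, abs=1e-12)

    def test_gradients_match_finite_differences(self):
        model = BilstmRelationClassifier(
            spec=BilstmSpec(max_tokens=4, embedding_dim=3, hidden_units=2),
            train_config=TrainConfig(seed=0),
        )
        _gradient_check(model, ["a b c", "c d", "b d a"], [1, 0, 1])


def _gradient_check(model, spans, labels, n_coords=5, eps=1e-6, tol=1e-5):
    """Finite-difference oracle for the analytic backward pass."""
    model.vocab = Vocabulary(spans)
    rng = np.random.default_rng(0)
    model.params = model._init_params(rng)
    # jitter away from exact zeros so finite differences never straddle a
    # ReLU kink or a max-pool tie (both exist at freshly zeroed biases)
    for k in model.params:
        model.params[k] = model.params[k] + rng.normal(0.0, 0.05, model.params[k].shape)
    enc = model._encode(spans)
    y = np.asarray(labels, dtype=float)

    def loss():
        probs, _ = model._forward(enc, train=False, rng=rng)
        return -np.mean(y * np.log(probs) + (1 - y) * np.log(1 - probs))

    probs, cache = model._forward(enc, train=False, rng=rng)
    grads = model._backward(cache, (probs - y) / len(y))
    check_rng = np.random.default_rng(1)
    for key, g in grads.items():
        flat = model.params[key].reshape(-1)
        gflat = np.asarray(g).reshape(-1)
        idxs = check_rng.choice(flat.size, size=min(n_coords, flat.size), replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss()
            flat[i] = orig - eps
            lm = loss()
            flat[i] = orig
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(gflat[i], abs=1e-6, rel=1e-3), key


class TestEmbeddings:
    def test_three_line_file(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("rash 1 0 0 0\ncolitis 0 1 0 0\nnivolumab 0 0 1 0\n")
        table = load_embeddings(path)
        assert len(table) == 3 and table.dim == 4

    def test_oov_zero_policy(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("rash 1 0\n")
        table = load_embeddings(path)
        assert table.lookup("unseen") == pytest.approx([0.0, 0.0])

    def test_oov_random_policy_cached_and_seeded(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("rash 1 0\n")
        t1 = load_embeddings(path, oov_policy="random", seed=5)
        t2 = load_embeddings(path, oov_policy="random", seed=5)
        v = t1.lookup("unseen")
        assert v == pytest.approx(t1.lookup("unseen"))  # cached
        assert v == pytest.approx(t2.lookup("unseen"))  # seeded
        assert not np.allclose(v, 0)

    def test_case_folding_flag(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("Rash 1 0\n")
        folded = load_embeddings(path, case_fold=True)
        assert folded.lookup("rash") == pytest.approx(folded.lookup("Rash"))
        exact = load_embeddings(path, case_fold=False)
        assert exact.lookup("rash") == pytest.approx([0.0, 0.0])

    def test_ragged_dimensions_error_names_line(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("a 1 2\nb 1 2 3\n")
        with pytest.raises(EmbeddingFormatError, match="line 2"):
            load_embeddings(path)


class TestRegistry:
    def test_in_tree_models_registered(self):
        assert {"svm", "cnn", "bilstm"} <= set(available_models())

    def test_unknown_model(self):
        with pytest.raises(KeyError, match="unknown model"):
            get_model("transformer-from-the-internet")

    def test_external_adapter_plug_point(self):
        from aderelex.models import register_model

        @register_model("constant-test-adapter")
        class Constant:
            def fit(self, spans, labels, val_spans=None, val_labels=None):
                return self

            def predict_scores(self, spans):
                return np.full(len(spans), 0.5)

        model = get_model("constant-test-adapter")
        assert model.fit([], []).predict_scores(["x"]) == pytest.approx([0.5])

    def test_empty_candidate_list_empty_predictions(self):
        assert predictions_from_scores([], np.zeros(0)) == []


class TestNoLeakage:
    def test_tfidf_vocabulary_from_training_folds_only(self):
        train = ["aa bb", "bb cc"]
        test = ["zz qq"]
        vec = CharNgramTfidf(NgramConfig(2, 2)).fit(train)
        test_grams = {"zz", "qq"}
        assert not (test_grams & set(vec.vocabulary))
        assert vec.transform(test).toarray().sum() == 0
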