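import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrminer.classifier import (
    ModelConfig,
    build_vocabulary,
    classify,
    encode_and_pad,
    load_model,
    predict_proba,
    save_model,
    split_train_test,
    train,
)
from adrminer.classifier.encoding import OOV_INDEX, VocabularyEncoding
from adrminer.classifier.model import _Network
from adrminer.embedding import train_embeddings

from util import tokenized


def _sentinel_posts(rng, n=80, sentinel="alarm"):
    """Linearly separable set: positives contain a sentinel token."""
    posts = []
    for i in range(n):
        label = int(i % 2 == 0)
        toks = [f"w{rng.integers(12)}" for _ in range(6)]
        if label:
            toks[int(rng.integers(len(toks)))] = sentinel
        posts.append(tokenized(toks, f"p{i}", label))
    return posts


def _small_cfg(**kw):
    base = dict(
        architecture="bilstm",
        hidden_units=8,
        embedding_dim=8,
        batch_size=16,
        epochs=10,
        seed=0,
    )
    base.update(kw)
    return ModelConfig(**base)


class TestVocabulary:
    def test_frequency_then_lexicographic(self):
        posts = [tokenized(["a", "a", "a", "b", "c"], "p0"), tokenized(["b", "c"], "p1")]
        enc = build_vocabulary(posts)
        assert enc.index == {"a": 2, "b": 3, "c": 4}

    def test_single_token_corpus(self):
        enc = build_vocabulary([tokenized(["only"], "p0")])
        assert enc.size == 3  # PAD + OOV + 1

    def test_deterministic(self):
        posts = [tokenized(list("abcabc"), "p0")]
        assert build_vocabulary(posts).index == build_vocabulary(posts).index

    def test_empty_error(self):
        with pytest.raises(ValueError):
            build_vocabulary([])


class TestEncodePad:
    ENC = VocabularyEncoding({"x": 2, "y": 3})

    def test_left_padding(self):
        [ep] = encode_and_pad([tokenized(["x", "y"], "p")], self.ENC, max_len=4)
        assert ep.sequence.tolist() == [0, 0, 2, 3]

    def test_oov_index(self):
        [ep] = encode_and_pad([tokenized(["unseen"], "p")], self.ENC, max_len=2)
        assert ep.sequence.tolist() == [0, OOV_INDEX]

    def test_tail_truncation(self):
        [ep] = encode_and_pad([tokenized(["x", "y", "x", "y"], "p")], self.ENC, max_len=2)
        assert ep.sequence.tolist() == [2, 3]  # first L tokens kept

    def test_auto_length(self):
        posts = [tokenized(["x"], "a"), tokenized(["x", "y", "x"], "b")]
        out = encode_and_pad(posts, self.ENC, max_len="auto")
        assert all(len(p.sequence) == 3 for p in out)


class TestSplit:
    def test_7_3_split(self):
        posts = [tokenized(["x"], f"p{i}", label=int(i < 5)) for i in range(10)]
        tr, te = split_train_test(posts, 0.7, seed=0)
        assert (len(tr), len(te)) == (7, 3)
        assert {p.post_id for p in tr}.isdisjoint({p.post_id for p in te})

    def test_stratification_at_table2_balance(self):
        n, n_pos = 576, 244  # 42.4% positive
        posts = [tokenized(["x"], f"p{i}", label=int(i < n_pos)) for i in range(n)]
        tr, te = split_train_test(posts, 0.7, seed=1)
        share = n_pos / n
        for part in (tr, te):
            got = sum(p.label for p in part) / len(part)
            assert abs(got - share) <= 1 / len(part)  # within 1 post of 42.4%

    def test_seed_reproducible(self):
        posts = [tokenized(["x"], f"p{i}", label=i % 2) for i in range(20)]
        a = split_train_test(posts, 0.7, seed=42)
        b = split_train_test(posts, 0.7, seed=42)
        assert [p.post_id for p in a[0]] == [p.post_id for p in b[0]]

    def test_small_class_error(self):
        posts = [tokenized(["x"], f"p{i}", label=int(i == 0)) for i in range(10)]
        with pytest.raises(ValueError, match="class"):
            split_train_test(posts, 0.7, seed=0)


@pytest.mark.parametrize("arch", ["bilstm", "gru", "cnn_bilstm"])
class TestTrainPerArchitecture:
    def test_separable_training_accuracy(self, arch):
        ok = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            posts = _sentinel_posts(rng)
            enc = build_vocabulary(posts)
            encoded = encode_and_pad(posts, enc)
            model = train(
                encoded, _small_cfg(architecture=arch, seed=seed, learning_rate=0.01), enc
            )
            preds = classify(predict_proba(model, encoded), 0.5)
            acc = (preds == np.array([p.label for p in encoded])).mean()
            ok += acc >= 0.95
        assert ok >= 4

    def test_gradients_match_numeric(self, arch):
        cfg = _small_cfg(architecture=arch, hidden_units=4, embedding_dim=5, conv_filters=6)
        net = _Network(cfg, vocab_size=9, embed_init=None)
        rng = np.random.default_rng(1)
        X = rng.integers(0, 9, (3, 7))
        y = np.array([1.0, 0.0, 1.0])
        p = net.forward(X)
        grads = net.backward(p, y)
        eps = 1e-6

        def loss():
            pr = net.forward(X)
            return float(-np.mean(y * np.log(pr + 1e-12) + (1 - y) * np.log(1 - pr + 1e-12)))

        for name, P in net.params().items():
            g = grads.get(name)
            if g is None:
                continue
            for _ in range(8):
                idx = tuple(int(rng.integers(0, s)) for s in P.shape)
                orig = P[idx]
                P[idx] = orig + eps
                lp = loss()
                P[idx] = orig - eps
                lm = loss()
                P[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(num, abs=1e-4, rel=1e-3)


class TestTrainContract:
    def test_epochs_zero_flagged_untrained(self):
        rng = np.random.default_rng(0)
        posts = _sentinel_posts(rng, n=20)
        enc = build_vocabulary(posts)
        encoded = encode_and_pad(posts, enc)
        model = train(encoded, _small_cfg(epochs=0), enc)
        assert model.trained is False
        scores = predict_proba(model, encoded)
        assert len(scores) == 20 and ((scores >= 0) & (scores <= 1)).all()

    def test_single_class_error(self):
        posts = [tokenized(["x"], f"p{i}", label=1) for i in range(8)]
        enc = build_vocabulary(posts)
        with pytest.raises(ValueError, match="single class"):
            train(encode_and_pad(posts, enc), _small_cfg(), enc)

    def test_seeded_losses_repeat_exactly(self):
        rng = np.random.default_rng(7)
        posts = _sentinel_posts(rng, n=40)
        enc = build_vocabulary(posts)
        encoded = encode_and_pad(posts, enc)
        cfg = _small_cfg(epochs=3, seed=5)
        l1 = [e["loss"] for e in train(encoded, cfg, enc).training_log]
        l2 = [e["loss"] for e in train(encoded, cfg, enc).training_log]
        assert l1 == pytest.approx(l2, abs=1e-4)

    def test_word2vec_initialization_and_freeze(self):
        rng = np.random.default_rng(3)
        posts = _sentinel_posts(rng, n=30)
        emb = train_embeddings(posts, dim=8, epochs=2, seed=3)
        enc = build_vocabulary(posts)
        encoded = encode_and_pad(posts, enc)
        cfg = _small_cfg(epochs=0, freeze_embeddings=True)
        model = train(encoded, cfg, enc)
        # untrained model with init vectors carries them verbatim
        model2 = train(encoded, cfg, enc, init_vectors=emb)
        term = next(t for t in enc.index if t in emb.vocabulary)
        row = enc.index[term]
        np.testing.assert_allclose(model2.network.E[row], emb.vector(term))
        assert not np.allclose(model.network.E[row], emb.vector(term))

    def test_dim_mismatch_error(self):
        rng = np.random.default_rng(3)
        posts = _sentinel_posts(rng, n=30)
        emb = train_embeddings(posts, dim=4, epochs=1, seed=3)
        enc = build_vocabulary(posts)
        with pytest.raises(ValueError, match="dim"):
            train(encode_and_pad(posts, enc), _small_cfg(embedding_dim=8), enc, init_vectors=emb)

    def test_early_stopping_records_val_loss(self):
        rng = np.random.default_rng(9)
        posts = _sentinel_posts(rng, n=60)
        enc = build_vocabulary(posts)
        encoded = encode_and_pad(posts, enc)
        model = train(encoded, _small_cfg(epochs=6, early_stopping=True, patience=2), enc)
        assert all("val_loss" in e for e in model.training_log)


class TestPredict:
    def _model_and_posts(self):
        rng = np.random.default_rng(2)
        posts = _sentinel_posts(rng, n=40)
        enc = build_vocabulary(posts)
        encoded = encode_and_pad(posts, enc)
        model = train(encoded, _small_cfg(epochs=2), enc)
        return model, encoded

    def test_scores_in_unit_interval(self):
        model, encoded = self._model_and_posts()
        s = predict_proba(model, encoded)
        assert ((s >= 0) & (s <= 1)).all()

    def test_duplicate_inputs_identical_scores(self):
        model, encoded = self._model_and_posts()
        s = predict_proba(model, [encoded[0], encoded[0]])
        assert s[0] == s[1]

    def test_batch_equals_single(self):
        model, encoded = self._model_and_posts()
        batch = predict_proba(model, encoded)
        singles = np.array([predict_proba(model, [p])[0] for p in encoded])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_length_mismatch_error(self):
        model, encoded = self._model_and_posts()
        bad = encode_and_pad([tokenized(["x"], "q")], model.encoding, max_len=model.max_len + 2)
        with pytest.raises(ValueError, match="length"):
            predict_proba(model, bad)


class TestClassify:
    def test_examples(self):
        assert classify(np.array([0.4, 0.5, 0.9]), 0.5).tolist() == [0, 1, 1]

    def test_threshold_one_all_negative(self):
        scores = np.array([0.2, 0.7, 0.999])
        assert classify(scores, 1.0).tolist() == [0, 0, 0]

    def test_threshold_zero_all_positive(self):
        assert classify(np.array([0.0, 0.3]), 0.0).tolist() == [1, 1]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            classify(np.array([0.5]), 1.5)

    @settings(max_examples=50, deadline=None)
    @given(
        scores=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        t1=st.floats(min_value=0, max_value=1),
        t2=st.floats(min_value=0, max_value=1),
    )
    def test_monotone_in_threshold(self, scores, t1, t2):
        lo, hi = sorted([t1, t2])
        s = np.array(scores)
        assert (classify(s, hi) <= classify(s, lo)).all()


def test_save_load_roundtrip(tmp_path):
    rng = np.random.default_rng(6)
    posts = _sentinel_posts(rng, n=30)
    enc = build_vocabulary(posts)
    encoded = encode_and_pad(posts, enc)
    model = train(encoded, _small_cfg(epochs=2), enc)
    again = load_model(save_model(model, tmp_path / "model"))
    np.testing.assert_allclose(
        predict_proba(model, encoded), predict_proba(again, encoded), atol=1e-12
    )
    assert again.config == model.config
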