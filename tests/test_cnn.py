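"""Embedding-layer modes, convolutional forward/backward and training."""

import numpy as np
import pytest

from orivec.cnn import (
    CNNConfig,
    OriCNN,
    aggregate_sibling_probs,
    build_embedding_layer,
)
from orivec.segmentation import build_vocabulary, encode, tokenize_records
from orivec.skipgram import EmbeddingMatrix
from orivec.synthetic import make_toy_fixture


def _random_embedding(vocab, dim, seed=0):
    rng = np.random.default_rng(seed)
    W = rng.normal(size=(len(vocab), dim))
    W[0] = 0.0
    return EmbeddingMatrix(W=W, vocab=vocab, metadata={"seed": seed})


@pytest.fixture(scope="module")
def small_emb():
    return _random_embedding(build_vocabulary("continuous"), dim=12)


class TestEmbeddingLayer:
    def test_default_mode_single_frozen_channel(self, small_emb):
        spec = build_embedding_layer(small_emb, "default")
        assert spec.num_channels == 1 and spec.trainable == [False]

    def test_embedding_training_mode_trainable(self, small_emb):
        spec = build_embedding_layer(small_emb, "embedding_training")
        assert spec.trainable == [True]

    def test_two_channel_mode(self, small_emb):
        spec = build_embedding_layer(small_emb, "two_channel")
        assert spec.num_channels == 2
        assert spec.trainable == [False, True]
        np.testing.assert_array_equal(spec.channels[0], spec.channels[1])

    def test_unknown_mode_errors(self, small_emb):
        with pytest.raises(ValueError, match="unknown"):
            build_embedding_layer(small_emb, "three_channel")

    def test_lookup_equals_one_hot_matmul(self, small_emb, rng):
        # embedding lookup must be bit-identical to one-hot(idx) @ W
        spec = build_embedding_layer(small_emb, "default")
        idx = rng.integers(0, len(small_emb.vocab), size=37)
        onehot = np.zeros((37, len(small_emb.vocab)))
        onehot[np.arange(37), idx] = 1.0
        looked = spec.lookup(idx)[0]
        np.testing.assert_array_equal(looked, onehot @ spec.channels[0])


class TestForward:
    def test_probabilities_sum_to_one(self, small_emb, rng):
        spec = build_embedding_layer(small_emb, "default")
        model = OriCNN(spec, l_max=20, config=CNNConfig(seed=0))
        idx = rng.integers(1, 65, size=(5, 20))
        probs = model.forward(idx, np.full(5, 20))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_pooled_dimension_is_filters_times_heights(self, small_emb, rng):
        cfg = CNNConfig(seed=0)
        assert cfg.pooled_dim == 128 * 3 == 384
        spec = build_embedding_layer(small_emb, "default")
        model = OriCNN(spec, l_max=16, config=cfg)
        idx = rng.integers(1, 65, size=(2, 16))
        _, cache = model._forward_batch(idx, np.full(2, 16), want_cache=True)
        assert cache["pooled"].shape == (2, 384)
        # one feature map per filter per height enters pooling
        assert sum(len(model.bK[h]) for h in cfg.kernel_heights) == 128 * 3

    def test_padding_is_masked(self, small_emb, rng):
        spec = build_embedding_layer(small_emb, "default")
        model = OriCNN(spec, l_max=30, config=CNNConfig(seed=1))
        tokens = rng.integers(1, 65, size=10)
        a = np.zeros((1, 30), dtype=int)
        a[0, :10] = tokens
        p1 = model.forward(a, np.array([10]))
        # same tokens, same true length, different amounts of trailing PAD
        model2 = OriCNN(spec, l_max=23, config=CNNConfig(seed=1))
        b = np.zeros((1, 23), dtype=int)
        b[0, :10] = tokens
        p2 = model2.forward(b, np.array([10]))
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_length_mismatch_errors(self, small_emb):
        spec = build_embedding_layer(small_emb, "default")
        model = OriCNN(spec, l_max=30)
        with pytest.raises(ValueError, match="L_max"):
            model.forward(np.zeros((1, 20), dtype=int), np.array([5]))


class TestBackward:
    def test_analytic_gradients_match_finite_differences(self, rng):
        """Full-network gradient check on a tiny configuration."""
        vocab = build_vocabulary("continuous")
        emb = _random_embedding(vocab, dim=5, seed=2)
        cfg = CNNConfig(kernel_heights=(2, 3), filters_per_height=3,
                        fc_units=4, l2_strength=1e-3, seed=0)
        spec = build_embedding_layer(emb, "two_channel")
        model = OriCNN(spec, l_max=7, config=cfg)
        idx = rng.integers(1, 65, size=(4, 7))
        lens = np.array([7, 5, 6, 7])
        y = np.array([0, 1, 1, 0])

        def loss():
            probs = model._forward_batch(idx, lens, want_cache=False)
            ce = -np.log(probs[np.arange(4), y]).mean()
            reg = 0.5 * cfg.l2_strength * (
                sum(np.sum(model.K[h] ** 2) for h in cfg.kernel_heights)
                + np.sum(model.FC1 ** 2) + np.sum(model.FC2 ** 2)
            )
            return ce + reg

        probs, cache = model._forward_batch(idx, lens, want_cache=True)
        grads = model._backward_batch(probs, cache, y)
        params = model._param_dict()
        eps = 1e-6
        for name in ("K2", "K3", "bK2", "FC1", "b1", "FC2", "b2", "W1"):
            p = params[name]
            flat = p.reshape(-1)
            for j in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                old = flat[j]
                flat[j] = old + eps
                up = loss()
                flat[j] = old - eps
                dn = loss()
                flat[j] = old
                num = (up - dn) / (2 * eps)
                assert grads[name].reshape(-1)[j] == pytest.approx(
                    num, abs=2e-5
                ), name

    def test_pad_row_never_receives_gradient(self, rng):
        vocab = build_vocabulary("continuous")
        emb = _random_embedding(vocab, dim=6, seed=3)
        spec = build_embedding_layer(emb, "embedding_training")
        model = OriCNN(spec, l_max=8,
                       config=CNNConfig(kernel_heights=(2,), filters_per_height=4,
                                        fc_units=4, seed=0))
        idx = rng.integers(1, 65, size=(3, 8))
        idx[:, 5:] = 0  # trailing PAD
        probs, cache = model._forward_batch(idx, np.array([5, 5, 5]), True)
        grads = model._backward_batch(probs, cache, np.array([1, 0, 1]))
        assert (grads["W0"][0] == 0).all()


@pytest.fixture(scope="module")
def toy_encoded():
    ds = make_toy_fixture()
    vocab = build_vocabulary("skip")
    sents = tokenize_records(ds.records, "skip")
    l_max = max(len(s) for s in sents)
    encoded, labels = [], []
    for s in sents:
        arr, n = encode(s, vocab, l_max)
        encoded.append(arr[:n])
        labels.append(s.label)
    return vocab, encoded, np.array(labels)


class TestTraining:
    def _fresh(self, vocab, mode, epochs=5, seed=0, dim=16):
        emb = _random_embedding(vocab, dim=dim, seed=seed)
        spec = build_embedding_layer(emb, mode)
        cfg = CNNConfig(filters_per_height=16, fc_units=24, epochs=epochs,
                        batch_size=16, seed=seed)
        return spec, OriCNN(spec, l_max=60, config=cfg)

    def test_default_mode_freezes_embedding(self, toy_encoded):
        vocab, encoded, labels = toy_encoded
        spec, model = self._fresh(vocab, "default")
        before = spec.channels[0].copy()
        model.fit(encoded, labels)
        np.testing.assert_array_equal(spec.channels[0], before)

    def test_embedding_training_updates_discriminative_rows(self, toy_encoded):
        vocab, encoded, labels = toy_encoded
        spec, model = self._fresh(vocab, "embedding_training")
        before = spec.channels[0].copy()
        model.fit(encoded, labels)
        seen = np.unique(np.concatenate(encoded))
        changed = np.linalg.norm(spec.channels[0] - before, axis=1)
        assert changed[seen].max() > 0  # corpus rows moved
        assert changed[0] == 0  # PAD row untouched

    def test_two_channel_freezes_exactly_one(self, toy_encoded):
        vocab, encoded, labels = toy_encoded
        spec, model = self._fresh(vocab, "two_channel")
        b0, b1 = spec.channels[0].copy(), spec.channels[1].copy()
        model.fit(encoded, labels)
        np.testing.assert_array_equal(spec.channels[0], b0)
        assert not np.array_equal(spec.channels[1], b1)

    def test_fixed_seed_reproduces_final_loss(self, toy_encoded):
        vocab, encoded, labels = toy_encoded
        _, m1 = self._fresh(vocab, "default", epochs=3, seed=5)
        _, m2 = self._fresh(vocab, "default", epochs=3, seed=5)
        m1.fit(encoded, labels)
        m2.fit(encoded, labels)
        assert m1.history[-1]["loss"] == m2.history[-1]["loss"]

    def test_single_class_errors(self, toy_encoded):
        vocab, encoded, labels = toy_encoded
        _, model = self._fresh(vocab, "default")
        with pytest.raises(ValueError, match="both classes"):
            model.fit(encoded, np.ones_like(labels))

    def test_toy_set_fits_perfectly_within_ten_epochs(self):
        # linearly separable composition: the full pipeline (pre-trained
        # embeddings + CNN, 10 epochs) classifies every training record
        from orivec.pipeline import OriPipeline, PipelineConfig
        from orivec.skipgram import SkipGramConfig

        ds = make_toy_fixture()
        cfg = PipelineConfig(
            segmentation="skip",
            embedding=SkipGramConfig(dim=50, epochs=3, seed=0),
            cnn=CNNConfig(epochs=10, seed=0),
            seed=0,
        )
        pipe = OriPipeline(cfg).fit(ds.records)
        preds = pipe.predict(ds.records)
        truth = np.array([r.label for r in ds.records])
        assert (preds == truth).mean() == 1.0


class TestAggregation:
    def test_mean_prob(self):
        probs = np.array([[0.1, 0.9], [0.2, 0.8], [0.3, 0.7]])
        scores, labels = aggregate_sibling_probs(probs, [7, 7, 7], "mean_prob")
        assert scores == pytest.approx([0.8])
        assert labels.tolist() == [1]

    def test_majority_vote(self):
        probs = np.array([[0.2, 0.8], [0.4, 0.6], [0.9, 0.1]])
        _, labels = aggregate_sibling_probs(probs, [0, 0, 0], "majority")
        assert labels.tolist() == [1]

    def test_per_derived_keeps_all(self):
        probs = np.array([[0.2, 0.8], [0.4, 0.6]])
        scores, labels = aggregate_sibling_probs(probs, [0, 0], "per_derived")
        assert len(scores) == 2 and labels.tolist() == [1, 1]

    def test_unknown_aggregation(self):
        with pytest.raises(ValueError, match="aggregation"):
            aggregate_sibling_probs(np.zeros((1, 2)), [0], "median")
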