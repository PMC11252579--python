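import numpy as np
import pytest

from crisislda.classifiers import (BilstmClassifier, CnnClassifier,
                                   FfnnClassifier, NeuralModelSpec,
                                   build_model, predict, train)
from crisislda.features import EncodedBatch

ARCHS = [FfnnClassifier, CnnClassifier, BilstmClassifier]


def _separable_batch(n=120, n_classes=3, length=8, vocab_per_class=5, seed=0):
    """Each class draws tokens from its own disjoint id block."""
    rng = np.random.default_rng(seed)
    v = n_classes * vocab_per_class
    ids = np.empty((n, length), np.int64)
    y = rng.integers(0, n_classes, size=n)
    for i in range(n):
        lo = y[i] * vocab_per_class
        ids[i] = rng.integers(lo, lo + vocab_per_class, size=length)
    mask = np.ones((n, length))
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    emb = rng.standard_normal((v, 16)) / 4.0
    batch = EncodedBatch(ids=ids, mask=mask, labels=onehot, pad_id=v)
    return batch, y, emb


class TestBuildAndInit:
    def test_ffnn_parameter_count_matches_arithmetic(self):
        rng = np.random.default_rng(0)
        emb = rng.standard_normal((40, 300))
        model = FfnnClassifier(embedding=emb, hidden=(64,), n_classes=10)
        model.initialize(10, max_len=20)
        assert model.n_parameters_ == 300 * 64 + 64 + 64 * 10 + 10

    def test_cnn_kernel_larger_than_max_len_rejected(self):
        rng = np.random.default_rng(0)
        emb = rng.standard_normal((10, 8))
        model = CnnClassifier(embedding=emb, kernel_size=9)
        with pytest.raises(ValueError, match="kernel_size"):
            model.initialize(3, max_len=5)

    @pytest.mark.parametrize("cls", ARCHS)
    def test_same_spec_and_seed_gives_identical_initial_weights(self, cls):
        rng = np.random.default_rng(1)
        emb = rng.standard_normal((12, 8))
        m1 = cls(embedding=emb, random_state=5).initialize(3, max_len=6)
        m2 = cls(embedding=emb, random_state=5).initialize(3, max_len=6)
        for k in m1.params_:
            np.testing.assert_array_equal(m1.params_[k], m2.params_[k])

    def test_build_model_dispatch_and_invalid_arch(self):
        spec = NeuralModelSpec("cnn", {"filter_count": 4})
        assert isinstance(build_model(spec), CnnClassifier)
        with pytest.raises(ValueError):
            NeuralModelSpec("transformer")

    def test_output_units_and_dropout_validated(self):
        emb = np.zeros((4, 4))
        with pytest.raises(ValueError, match="output_units"):
            FfnnClassifier(embedding=emb).initialize(1)
        with pytest.raises(ValueError, match="dropout_rate"):
            FfnnClassifier(embedding=emb, dropout_rate=1.0).initialize(3)


class TestTraining:
    def test_ffnn_fits_linearly_separable_data(self):
        batch, y, emb = _separable_batch()
        model = FfnnClassifier(embedding=emb, hidden=(32,), epochs=30,
                               dropout_rate=0.0, learning_rate=1e-2,
                               random_state=0)
        model.fit(batch, y)
        assert model.history_[-1]["train_acc"] >= 0.99

    def test_zero_epochs_keeps_initial_weights_and_empty_history(self):
        batch, y, emb = _separable_batch()
        model = FfnnClassifier(embedding=emb, epochs=0, random_state=3)
        model.fit(batch, y)
        ref = FfnnClassifier(embedding=emb, random_state=3).initialize(
            3, max_len=batch.ids.shape[1])
        assert model.history_ == []
        for k in ref.params_:
            np.testing.assert_array_equal(model.params_[k], ref.params_[k])

    @pytest.mark.parametrize("cls", ARCHS)
    def test_loss_decreases_on_memorizable_set(self, cls):
        batch, y, emb = _separable_batch(n=40, seed=2)
        model = cls(embedding=emb, epochs=12, dropout_rate=0.0,
                    batch_size=40, random_state=1)
        model.fit(batch, y)
        losses = [h["train_loss"] for h in model.history_]
        assert losses[-1] < losses[0]

    @pytest.mark.parametrize("cls", ARCHS)
    def test_seeded_training_is_bitwise_reproducible(self, cls):
        batch, y, emb = _separable_batch(n=60, seed=4)
        kw = dict(embedding=emb, epochs=2, random_state=11)
        m1 = cls(**kw).fit(batch, y)
        m2 = cls(**kw).fit(batch, y)
        for k in m1.params_:
            np.testing.assert_array_equal(m1.params_[k], m2.params_[k])
        np.testing.assert_array_equal(m1.predict_proba(batch),
                                      m2.predict_proba(batch))

    def test_label_dimension_mismatch_rejected(self):
        batch, y, emb = _separable_batch()
        model = FfnnClassifier(embedding=emb, n_classes=7, epochs=1)
        with pytest.raises(ValueError, match="label dimension"):
            model.fit(batch)  # batch carries 3-class one-hot labels

    def test_validation_history_recorded(self):
        batch, y, emb = _separable_batch(n=80)
        model = FfnnClassifier(embedding=emb, epochs=3, random_state=0)
        model.fit(batch, y, validation=(batch, y))
        assert {"val_loss", "val_acc"} <= set(model.history_[0])

    def test_functional_train_wrapper(self):
        batch, y, emb = _separable_batch(n=50)
        model = FfnnClassifier(embedding=emb)
        out = train(model, batch, epochs=2, seed=9)
        assert len(out.history_) == 2


class TestPredict:
    def test_scores_are_sigmoid_not_softmax(self):
        batch, y, emb = _separable_batch(n=50)
        model = FfnnClassifier(embedding=emb, epochs=5,
                               random_state=0).fit(batch, y)
        scores, labels = predict(model, batch)
        assert scores.shape == (50, 3)
        assert np.all((scores > 0) & (scores < 1))
        # multilabel head: rows need not normalize
        assert not np.allclose(scores.sum(axis=1), 1.0)

    def test_argmax_tie_breaks_to_smallest_index(self):
        scores = np.array([[0.5, 0.5, 0.2], [0.1, 0.9, 0.3]])
        assert np.argmax(scores, axis=1).tolist() == [0, 1]

    def test_checkpoint_round_trip(self, tmp_path):
        batch, y, emb = _separable_batch(n=40)
        model = FfnnClassifier(embedding=emb, epochs=2,
                               random_state=0).fit(batch, y)
        path = str(tmp_path / "model.npz")
        model.save(path)
        clone = FfnnClassifier(embedding=emb)
        clone.load_weights(path)
        np.testing.assert_array_equal(model.predict_proba(batch),
                                      clone.predict_proba(batch))
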