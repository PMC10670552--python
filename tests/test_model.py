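"""The CNN-LSTM classifier: config validation, training, persistence."""

import numpy as np
import pytest

import ecgqual as eq
from ecgqual.datasets import split
from ecgqual.errors import ConfigError, DataError, ModelStoreError
from ecgqual.evaluate import evaluate_model
from ecgqual.model import (
    ModelConfig,
    build_model,
    corpus_to_arrays,
    load_model,
    predict,
    save_model,
    train,
)
from ecgqual.signal_io import QualityLabel


class TestModelConfig:
    def test_boundary_dropout(self):
        assert ModelConfig(dropout_rate=0.99).dropout_rate == 0.99
        with pytest.raises(ConfigError):
            ModelConfig(dropout_rate=1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"learning_rate": 0.0},
            {"output_units": 3},
            {"loss": "hinge"},
            {"loss": "binary_cross_entropy", "output_units": 2},
            {"loss": "sparse_categorical_cross_entropy", "output_units": 1},
            {"conv_blocks": ((64, 3),) * 6},  # pooling eats the whole time axis
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ConfigError):
            ModelConfig(**kwargs)

    def test_sigmoid_variant_accepted(self):
        cfg = ModelConfig(loss="binary_cross_entropy", output_units=1)
        assert cfg.output_units == 1


class TestBuildAndPredict:
    def test_softmax_probabilities_sum_to_one(self):
        net = build_model(ModelConfig(seed=3))
        x = np.random.default_rng(0).standard_normal((4, 38, 129))
        from ecgqual._nn import softmax

        probs = softmax(net.forward(x))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-12)
        assert np.all(probs >= 0)

    def test_sigmoid_head_probabilities_in_unit_interval(self, small_split):
        tr, va, _ = small_split
        cfg = ModelConfig(loss="binary_cross_entropy", output_units=1, epochs=2, seed=3)
        trained = train(build_model(cfg), tr, va, cfg)
        xs, _ = corpus_to_arrays(tr, cfg)
        for _, p in predict(trained, list(xs[:8])):
            assert 0.0 <= p <= 1.0

    def test_epochs_zero_gives_initialized_model(self, small_split):
        tr, va, _ = small_split
        cfg = ModelConfig(epochs=0, seed=11)
        trained = train(build_model(cfg), tr, va, cfg)
        assert trained.history["loss"] == []
        xs, _ = corpus_to_arrays(tr, cfg)
        preds = predict(trained, list(xs[:4]))
        again = predict(train(build_model(cfg), tr, va, cfg), list(xs[:4]))
        assert preds == again

    def test_tie_goes_to_unacceptable(self, trained_small_model, test_corpus):
        xs, _ = corpus_to_arrays(test_corpus, trained_small_model.config)
        (label, p) = predict(trained_small_model, [xs[0]])[0]
        # threshold exactly at the returned probability: p > p is false
        (tied_label, _) = predict(trained_small_model, [xs[0]], threshold=p)[0]
        assert tied_label == QualityLabel.UNACCEPTABLE

    def test_empty_input_list(self, trained_small_model):
        assert predict(trained_small_model, []) == []

    def test_shape_mismatch_names_record(self, trained_small_model):
        with pytest.raises(DataError, match="record 0"):
            predict(trained_small_model, [np.zeros((10, 10))])


class TestTraining:
    def test_separable_corpus_reaches_high_validation_accuracy(self, trained_small_model):
        assert trained_small_model.history["val_accuracy"][-1] >= 0.95

    def test_loss_finite_every_epoch(self, trained_small_model):
        assert all(np.isfinite(v) for v in trained_small_model.history["loss"])
        assert all(np.isfinite(v) for v in trained_small_model.history["val_loss"])

    def test_identical_seeds_reproduce_history(self):
        corpus = eq.make_labeled_corpus(60, 0.5, seed=21)
        tr, va, _ = split(corpus, (0.8, 0.2, 0.0), seed=21)
        cfg = ModelConfig(epochs=3, seed=21)
        h1 = train(build_model(cfg), tr, va, cfg).history
        h2 = train(build_model(cfg), tr, va, cfg).history
        assert h1 == h2

    def test_f1_improves_with_snr_gap(self):
        """Widening the SNR gap between classes makes the task easier;
        held-out F1 tracks it (small slack absorbs one-segment jitter)."""
        f1s = []
        for gap in (5, 10, 20):
            corpus = eq.make_labeled_corpus(
                300, 0.5, snr_acceptable_db=5.0, snr_unacceptable_db=5.0 - gap, seed=77
            )
            test = eq.make_labeled_corpus(
                200, 0.5, snr_acceptable_db=5.0, snr_unacceptable_db=5.0 - gap, seed=1077
            )
            tr, va, _ = split(corpus, (0.85, 0.15, 0.0), seed=77)
            cfg = ModelConfig(epochs=12, seed=77)
            trained = train(build_model(cfg), tr, va, cfg)
            f1s.append(evaluate_model(trained, test).f1)
        assert f1s[0] <= f1s[1] + 2.0
        assert f1s[1] <= f1s[2] + 2.0
        assert f1s[2] >= 90.0


class TestPersistence:
    def test_round_trip_predictions_bitwise_equal(self, trained_small_model, test_corpus, tmp_path):
        path = tmp_path / "model.ecgm"
        save_model(trained_small_model, path)
        loaded = load_model(path)
        xs, _ = corpus_to_arrays(test_corpus, trained_small_model.config)
        assert predict(trained_small_model, list(xs[:10])) == predict(loaded, list(xs[:10]))
        assert loaded.history == trained_small_model.history

    def test_save_twice_identical_bytes(self, trained_small_model, tmp_path):
        p1, p2 = tmp_path / "a.ecgm", tmp_path / "b.ecgm"
        save_model(trained_small_model, p1)
        save_model(trained_small_model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_corrupt_store_rejected(self, tmp_path):
        path = tmp_path / "bad.ecgm"
        path.write_bytes(b"not a model at all\x00\x01")
        with pytest.raises(ModelStoreError):
            load_model(path)

    def test_version_mismatch_rejected(self, trained_small_model, tmp_path):
        path = tmp_path / "model.ecgm"
        save_model(trained_small_model, path)
        raw = path.read_bytes()
        path.write_bytes(raw.replace(b'"version": 1', b'"version": 99', 1))
        with pytest.raises(ModelStoreError, match="version"):
            load_model(path)

    def test_truncated_blob_rejected(self, trained_small_model, tmp_path):
        path = tmp_path / "model.ecgm"
        save_model(trained_small_model, path)
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) - 1000])
        with pytest.raises(ModelStoreError, match="truncated"):
            load_model(path)
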