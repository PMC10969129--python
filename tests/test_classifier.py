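import numpy as np
import pytest

from alshift.classifier import (
    ArchConfig,
    TrainConfig,
    build_classifier,
    grad_cam,
    load_snapshot,
    predict_proba,
    restore,
    save_snapshot,
    snapshot,
    train,
    weights_digest,
)
from alshift.data_io import CLASS0, ImageSample
from alshift.errors import ConfigurationError, TrainingError
from alshift.synthetic import generate_domain


class TestTrainConfigDefaults:
    def test_published_protocol_defaults(self):
        cfg = TrainConfig()
        assert cfg.batch_size == 32
        assert cfg.max_epochs == 30
        assert cfg.optimizer == "adagrad"
        assert cfg.learning_rate == 0.001
        assert cfg.loss == "categorical_cross_entropy"
        assert cfg.activation == "relu"

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(batch_size=0).validate()
        with pytest.raises(ConfigurationError):
            TrainConfig(learning_rate=-1).validate()
        with pytest.raises(ConfigurationError):
            TrainConfig(optimizer="sgd").validate()


class TestBuild:
    def test_same_seed_identical_weights(self, small_arch):
        a = build_classifier(small_arch, TrainConfig(seed=42))
        b = build_classifier(small_arch, TrainConfig(seed=42))
        for k, v in a.net.get_weights().items():
            assert np.array_equal(v, b.net.get_weights()[k]), k

    def test_different_seed_different_weights(self, small_arch):
        a = build_classifier(small_arch, TrainConfig(seed=1))
        b = build_classifier(small_arch, TrainConfig(seed=2))
        assert any(
            not np.array_equal(v, b.net.get_weights()[k])
            for k, v in a.net.get_weights().items()
        )

    def test_fresh_head_predicts_half(self, small_arch):
        state = build_classifier(small_arch, TrainConfig(seed=0))
        x = np.random.default_rng(0).uniform(size=(5, 16, 16, 3)).astype(np.float32)
        assert np.allclose(predict_proba(state, x), 0.5)

    def test_input_size_mismatch_rejected(self, small_arch):
        state = build_classifier(small_arch, TrainConfig(seed=0))
        with pytest.raises(ConfigurationError):
            predict_proba(state, np.zeros((1, 32, 32, 3), dtype=np.float32))


class TestTrain:
    def test_separable_toy_reaches_095_at_three_seeds(self, easy_spec, small_arch):
        ds = generate_domain(easy_spec)
        for seed in range(3):
            cfg = TrainConfig(max_epochs=25, learning_rate=0.05, seed=seed)
            state = build_classifier(small_arch, cfg)
            train(state, ds.train, cfg)
            assert state.train_history[-1]["accuracy"] >= 0.95, f"seed {seed}"

    def test_final_loss_not_above_first(self, easy_spec, small_arch):
        ds = generate_domain(easy_spec)
        cfg = TrainConfig(max_epochs=15, learning_rate=0.05, seed=0)
        state = build_classifier(small_arch, cfg)
        train(state, ds.train, cfg)
        assert state.train_history[-1]["loss"] <= state.train_history[0]["loss"]

    def test_zero_epochs_leaves_weights_unchanged(self, tiny_dataset, small_arch):
        cfg = TrainConfig(max_epochs=0, seed=0)
        state = build_classifier(small_arch, cfg)
        before = state.net.get_weights()
        train(state, tiny_dataset.train, cfg)
        for k, v in state.net.get_weights().items():
            assert np.array_equal(v, before[k])

    def test_single_class_rejected(self, tiny_dataset, small_arch):
        cfg = TrainConfig(max_epochs=1, seed=0)
        state = build_classifier(small_arch, cfg)
        one_class = [s for s in tiny_dataset.train if s.label == CLASS0]
        with pytest.raises(TrainingError):
            train(state, one_class, cfg)

    def test_empty_input_rejected(self, small_arch):
        cfg = TrainConfig(max_epochs=1, seed=0)
        state = build_classifier(small_arch, cfg)
        with pytest.raises(ValueError):
            train(state, [], cfg)

    def test_training_is_reproducible(self, tiny_dataset, small_arch):
        def fit():
            cfg = TrainConfig(max_epochs=3, learning_rate=0.05, seed=9)
            state = build_classifier(small_arch, cfg)
            return train(state, tiny_dataset.train, cfg)

        a, b = fit(), fit()
        assert weights_digest(a) == weights_digest(b)
        assert a.train_history == b.train_history

    def test_warm_start_changes_weights(self, tiny_dataset, small_arch):
        cfg = TrainConfig(max_epochs=2, learning_rate=0.05, seed=0)
        state = build_classifier(small_arch, cfg)
        train(state, tiny_dataset.train, cfg)
        digest_before = weights_digest(state)
        train(state, tiny_dataset.train, cfg)
        assert weights_digest(state) != digest_before


class TestPredict:
    def test_probability_pairs_sum_to_one(self, small_arch, tiny_dataset):
        cfg = TrainConfig(max_epochs=2, learning_rate=0.05, seed=0)
        state = build_classifier(small_arch, cfg)
        train(state, tiny_dataset.train, cfg)
        from alshift.data_io import stack_pixels

        x = stack_pixels(tiny_dataset.test).transpose(0, 3, 1, 2)
        pairs = state.net.predict_proba(np.ascontiguousarray(x))
        assert np.allclose(pairs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_samples_get_identical_scores(self, small_arch, tiny_dataset):
        cfg = TrainConfig(max_epochs=2, learning_rate=0.05, seed=0)
        state = build_classifier(small_arch, cfg)
        train(state, tiny_dataset.train, cfg)
        s = tiny_dataset.test[0]
        p = predict_proba(state, [s, tiny_dataset.test[1], s])
        assert p[0] == p[2]

    def test_pure_function_of_pixels(self, small_arch, tiny_dataset):
        cfg = TrainConfig(max_epochs=2, learning_rate=0.05, seed=0)
        state = build_classifier(small_arch, cfg)
        train(state, tiny_dataset.train, cfg)
        p1 = predict_proba(state, tiny_dataset.test)
        p2 = predict_proba(state, tiny_dataset.test)
        assert np.array_equal(p1, p2)


class TestSnapshots:
    def test_restore_round_trip_bit_identical(self, small_arch, tiny_dataset):
        cfg = TrainConfig(max_epochs=2, learning_rate=0.05, seed=0)
        state = build_classifier(small_arch, cfg)
        train(state, tiny_dataset.train, cfg)
        p_before = predict_proba(state, tiny_dataset.test)
        snap = snapshot(state, tag="w1")
        train(state, tiny_dataset.train, cfg)  # perturb
        restore(state, snap, tag="w1")
        assert np.array_equal(predict_proba(state, tiny_dataset.test), p_before)

    def test_save_load_file_round_trip(self, tmp_path, small_arch, tiny_dataset):
        cfg = TrainConfig(max_epochs=2, learning_rate=0.05, seed=0)
        state = build_classifier(small_arch, cfg)
        train(state, tiny_dataset.train, cfg)
        state.weights_tag = "w1"
        path = save_snapshot(state, tmp_path / "w1.npz")
        loaded = load_snapshot(path)
        assert loaded.weights_tag == "w1"
        assert loaded.arch_config == small_arch
        assert np.array_equal(
            predict_proba(loaded, tiny_dataset.test),
            predict_proba(state, tiny_dataset.test),
        )


class TestGradCam:
    def test_zero_head_gives_zero_heatmap(self, small_arch, tiny_dataset):
        state = build_classifier(small_arch, TrainConfig(seed=0))
        cam = grad_cam(state, tiny_dataset.test[0])
        assert np.array_equal(cam, np.zeros_like(cam))

    def test_heatmap_nonnegative_and_input_sized(self, small_arch, tiny_dataset):
        cfg = TrainConfig(max_epochs=2, learning_rate=0.05, seed=0)
        state = build_classifier(small_arch, cfg)
        train(state, tiny_dataset.train, cfg)
        cam = grad_cam(state, tiny_dataset.test[0])
        h, w, _ = small_arch.input_size
        assert cam.shape == (h, w)
        assert cam.min() >= 0.0
        assert cam.max() <= 1.0 + 1e-6

    def test_missing_layer_rejected(self, small_arch, tiny_dataset):
        state = build_classifier(small_arch, TrainConfig(seed=0))
        with pytest.raises(ConfigurationError, match="no layer"):
            grad_cam(state, tiny_dataset.test[0], target_layer="conv99")

    def test_one_filter_toy_matches_analytic_chain_rule(self):
        """Hand-built single-conv-filter net vs. explicit chain-rule oracle."""
        arch = ArchConfig(input_size=(4, 4, 1), conv_filters=(1,), kernel_size=3)
        state = build_classifier(arch, TrainConfig(seed=0))
        net = state.net
        W = np.zeros((1, 1, 3, 3), dtype=np.float32)
        W[0, 0, 1, 1] = 2.0  # identity-ish filter
        net.params()["conv1.W"][...] = W
        net.params()["head.W"][...] = np.array([[0.0, 1.0]], dtype=np.float32)

        x = np.zeros((4, 4, 1), dtype=np.float32)
        x[1, 2, 0] = 1.0  # one-hot input

        # analytic oracle (explicit chain rule, independent of the engine):
        xc = x[:, :, 0] - 0.5  # fixed input centering
        A = 2.0 * xc  # conv with the identity filter, zero bias
        relu_mask = (A > 0).astype(np.float64)
        pooled = np.maximum.reduce([A[i::2, j::2] for i in range(2) for j in range(2)])
        win = A.reshape(2, 2, 2, 2).transpose(0, 2, 1, 3)
        # d logit1 / d A: head weight 1.0, GAP over 2x2 = /4, through max mask
        dA = np.zeros_like(A)
        for pi in range(2):
            for pj in range(2):
                blk = win[pi, pj]
                mask = (blk == pooled[pi, pj]) & (blk > 0)
                dA[2 * pi:2 * pi + 2, 2 * pj:2 * pj + 2] += mask / 4.0
        alpha = dA.mean()
        cam_expected = np.maximum(alpha * A, 0.0)
        if cam_expected.max() > 0:
            cam_expected = cam_expected / cam_expected.max()

        cam = grad_cam(state, x, target_layer="conv1", target_class=1)
        assert cam.shape == (4, 4)
        assert np.unravel_index(cam.argmax(), cam.shape) == np.unravel_index(
            cam_expected.argmax(), cam_expected.shape
        )
        assert np.allclose(cam, cam_expected, atol=1e-5)
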