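import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deeplof.engine import DegenerateFeatureError
from deeplof.network import (FeatureDescriptor, L2HeadConfig, TrainingConfig,
                             binary_score, build_model, extract_features,
                             l2_constrain, l2_softmax_loss, predict_softmax, train)
from deeplof.augment import AugmentConfig

from conftest import toy_three_class_set


TOY_CFG = TrainingConfig(backbone="tiny_cnn", input_size=12, feature_dim=16,
                         learning_rate=1e-2, max_epochs=20, early_stop_patience=20,
                         seed=0, frozen_layers=0)
TOY_HEAD = L2HeadConfig(alpha=80.0, n_classes=3)


class TestL2Constrain:
    def test_three_four_five_triangle(self):
        np.testing.assert_allclose(l2_constrain(np.array([3.0, 4.0]), 80.0),
                                   [48.0, 64.0])

    def test_fixed_point(self, rng):
        x = rng.normal(size=6)
        x = 80.0 * x / np.linalg.norm(x)
        np.testing.assert_allclose(l2_constrain(x, 80.0), x, rtol=1e-6)

    def test_default_scale_norm(self, rng):
        for _ in range(10):
            x = rng.normal(size=rng.integers(2, 30))
            assert np.linalg.norm(l2_constrain(x, 80.0)) == pytest.approx(80.0, rel=1e-9)

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateFeatureError):
            l2_constrain(np.zeros(5), 80.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 100), c=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, seed, c):
        x = np.random.default_rng(seed).normal(size=8)
        np.testing.assert_allclose(l2_constrain(c * x, 80.0), l2_constrain(x, 80.0),
                                   rtol=1e-9, atol=1e-9)


class TestL2SoftmaxLoss:
    def test_uniform_head_gives_log_c(self, rng):
        W = np.zeros((6, 3))
        b = np.zeros(3)
        x = l2_constrain(rng.normal(size=6), 80.0)
        assert l2_softmax_loss(x, np.array([1]), W, b) == pytest.approx(np.log(3.0))

    def test_closed_form_single_sample(self):
        # logits (10, 0, 0), true class 0 -> loss = log(1 + 2 e^{-10})
        W = np.array([[10.0, 0.0, 0.0]])
        b = np.zeros(3)
        loss = l2_softmax_loss(np.array([[1.0]]), np.array([0]), W, b)
        assert loss == pytest.approx(np.log(1 + 2 * np.exp(-10.0)), rel=1e-12)

    def test_soft_labels_reduce_to_hard(self, rng):
        W = rng.normal(size=(5, 3))
        b = rng.normal(size=3)
        x = np.stack([l2_constrain(rng.normal(size=5), 80.0) for _ in range(4)])
        labels = np.array([0, 2, 1, 0])
        one_hot = np.zeros((4, 3))
        one_hot[np.arange(4), labels] = 1.0
        assert l2_softmax_loss(x, labels, W, b) == pytest.approx(
            l2_softmax_loss(x, one_hot, W, b), rel=1e-12)

    def test_invalid_labels_rejected(self, rng):
        W = rng.normal(size=(4, 3))
        x = l2_constrain(rng.normal(size=4), 80.0)
        with pytest.raises(ValueError):
            l2_softmax_loss(x, np.array([5]), W, np.zeros(3))
        with pytest.raises(ValueError):
            l2_softmax_loss(x, np.array([[0.5, 0.1, 0.1]]), W, np.zeros(3))

    def test_head_gradient_matches_finite_differences(self, rng):
        W = rng.normal(size=(4, 3))
        b = rng.normal(size=3)
        x = np.stack([l2_constrain(rng.normal(size=4), 5.0) for _ in range(3)])
        labels = np.array([0, 1, 2])
        # analytic: dW = x^T (softmax - onehot) / M
        logits = x @ W + b
        p = np.exp(logits - logits.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        t = np.zeros_like(p)
        t[np.arange(3), labels] = 1.0
        dW = x.T @ (p - t) / 3
        eps = 1e-6
        for _ in range(5):
            i, j = rng.integers(0, 4), rng.integers(0, 3)
            old = W[i, j]
            W[i, j] = old + eps
            lp = l2_softmax_loss(x, labels, W, b)
            W[i, j] = old - eps
            lm = l2_softmax_loss(x, labels, W, b)
            W[i, j] = old
            assert dW[i, j] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-9)


class TestBuildModel:
    def test_tiny_forward_is_simplex(self, rng):
        model = build_model(TrainingConfig(input_size=100), L2HeadConfig())
        probs = model.predict_proba(rng.uniform(0, 1, (2, 100, 100, 3)))
        assert probs.shape == (2, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-6)

    def test_feature_norm_equals_alpha(self, rng):
        model = build_model(TOY_CFG, TOY_HEAD)
        feats = model.features(rng.uniform(0, 1, (3, 12, 12, 3)))
        np.testing.assert_allclose(np.linalg.norm(feats, axis=1), 80.0, rtol=1e-6)

    def test_vgg16_freezing_and_constraint(self, rng):
        cfg = TrainingConfig(backbone="vgg16_transfer", input_size=32)
        model = build_model(cfg, L2HeadConfig(alpha=80.0))
        weight_layers = model.weight_layers()
        assert len(weight_layers) == 16  # 13 conv + 2 fc + classifier
        frozen = [all(not p.trainable for p in ly.params()) for ly in weight_layers]
        assert frozen == [True] * 10 + [False] * 6
        feats = model.features(rng.uniform(0, 1, (1, 32, 32, 3)).astype(np.float32))
        assert np.linalg.norm(feats) == pytest.approx(80.0, rel=1e-5)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(backbone="resnet50")


class TestTraining:
    def test_loss_decreases_on_separable_toy(self):
        items = toy_three_class_set()
        model = build_model(TOY_CFG, TOY_HEAD)
        trained = train(model, items, items[:6], config=TOY_CFG)
        hist = trained.history
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_training_accuracy_on_separable_toy(self):
        items = toy_three_class_set()
        model = build_model(TOY_CFG, TOY_HEAD)
        trained = train(model, items, items[:6], config=TOY_CFG)
        probs = predict_softmax(trained, items)
        labels = np.array([it.label for it in items])
        assert (probs.argmax(axis=1) == labels).mean() >= 0.9

    def test_early_stopping_rule(self):
        items = toy_three_class_set(n_per_class=4)
        cfg = TrainingConfig(backbone="tiny_cnn", input_size=12, feature_dim=8,
                             learning_rate=10.0, max_epochs=50,
                             early_stop_patience=0, seed=1, frozen_layers=0)
        model = build_model(cfg, TOY_HEAD)
        trained = train(model, items, items[:3], config=cfg)
        hist = trained.history
        assert len(hist) < 50
        assert trained.best_epoch == int(hist["val_loss"].idxmin()) + 1

    def test_seed_determinism(self):
        items = toy_three_class_set(n_per_class=3)
        cfg = TrainingConfig(backbone="tiny_cnn", input_size=12, feature_dim=8,
                             learning_rate=1e-2, max_epochs=4,
                             early_stop_patience=4, seed=5, frozen_layers=0)
        weights = []
        for _ in range(2):
            model = build_model(cfg, TOY_HEAD)
            train(model, items, items[:3], augment_config=AugmentConfig(seed=5),
                  config=cfg)
            weights.append(model.state())
        for a, b in zip(*weights):
            np.testing.assert_array_equal(a, b)

    def test_frozen_layers_bit_identical_after_training(self):
        items = toy_three_class_set(n_per_class=3)
        cfg = TrainingConfig(backbone="tiny_cnn", input_size=12, feature_dim=8,
                             learning_rate=1e-2, max_epochs=3,
                             early_stop_patience=3, seed=2, frozen_layers=2)
        model = build_model(cfg, TOY_HEAD)
        frozen_before = [p.value.copy() for ly in model.weight_layers()[:2]
                         for p in ly.params()]
        train(model, items, items[:3], config=cfg)
        frozen_after = [p.value for ly in model.weight_layers()[:2]
                        for p in ly.params()]
        for a, b in zip(frozen_before, frozen_after):
            np.testing.assert_array_equal(a, b)

    def test_empty_validation_rejected(self):
        items = toy_three_class_set(n_per_class=2)
        model = build_model(TOY_CFG, TOY_HEAD)
        with pytest.raises(ValueError, match="validation"):
            train(model, items, [], config=TOY_CFG)


class TestExtraction:
    def test_descriptor_norms_and_dim(self):
        items = toy_three_class_set(n_per_class=2)
        model = build_model(TOY_CFG, TOY_HEAD)
        descs = extract_features(model, items)
        assert all(isinstance(d, FeatureDescriptor) for d in descs)
        assert all(d.x.shape == (16,) for d in descs)
        for d in descs:
            assert np.linalg.norm(d.x) == pytest.approx(80.0, rel=1e-5)

    def test_duplicate_inputs_identical_descriptors(self):
        items = toy_three_class_set(n_per_class=1)
        model = build_model(TOY_CFG, TOY_HEAD)
        d1, d2 = extract_features(model, [items[0], items[0]])
        np.testing.assert_array_equal(d1.x, d2.x)

    def test_binary_score_renormalization(self, rng):
        probs = rng.dirichlet(np.ones(3), size=20)
        s = binary_score(probs)
        assert np.all((s >= 0) & (s <= 1))
        np.testing.assert_allclose(s, probs[:, 1] / (probs[:, 0] + probs[:, 1]))
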