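"""CNN contract: architecture arithmetic, gradient correctness, weighted
loss identities, determinism and learnability."""

import numpy as np
import pytest

from mitransfer.cnn import CnnConfig, build_model, predict, train

# Layer-by-layer parameter arithmetic for the default architecture,
# computed by hand from the shape chain
# (64,64,3)->(64,64,8)->(32,32,8)->(32,32,8)->(16,16,8)->10->2:
#   conv1: 3*3*3*8 + 8   = 224
#   conv2: 3*3*8*8 + 8   = 584
#   dense1: 16*16*8*10+10 = 20490
#   dense2: 10*2 + 2     = 22
EXPECTED_PARAMS = 224 + 584 + 20490 + 22  # = 21320

TINY = CnnConfig(input_shape=(8, 8, 3), dropout_rate=0.0, seed=3)


def _tiny_batch(n=6, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 8, 8, 3))
    y = np.arange(n) % 2
    return X, y


class TestArchitecture:
    def test_parameter_count_matches_hand_arithmetic(self):
        model = build_model(CnnConfig())
        assert model.n_parameters == EXPECTED_PARAMS
        assert CnnConfig().n_parameters == EXPECTED_PARAMS

    def test_same_seed_identical_initial_weights(self):
        a, b = build_model(CnnConfig(seed=5)), build_model(CnnConfig(seed=5))
        for name in a.params:
            np.testing.assert_array_equal(a.params[name], b.params[name])

    def test_softmax_rows_sum_to_one(self):
        model = build_model(CnnConfig(seed=1))
        X = np.random.default_rng(2).random((4, 64, 64, 3))
        _, probs = predict(model, X)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inconsistent_shape_chain_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            CnnConfig(input_shape=(30, 30, 3))

    def test_wrong_input_shape_rejected(self):
        model = build_model(CnnConfig(seed=0))
        with pytest.raises(ValueError, match="shape"):
            predict(model, np.zeros((2, 32, 32, 3)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central finite differences for a
        few entries of every parameter tensor (float64 model)."""
        model = build_model(TINY, dtype=np.float64)
        X, y = _tiny_batch()
        w = np.array([1.0, 0.7, 0.9, 0.5, 1.0, 0.3])
        _, grads = model.loss_and_grads(X, y, w, train_mode=False)
        eps = 1e-6
        rng = np.random.default_rng(0)
        for name, P in model.params.items():
            flat = P.reshape(-1)
            for j in rng.choice(P.size, size=min(4, P.size), replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                lp, _ = model.loss_and_grads(X, y, w, train_mode=False)
                flat[j] = orig - eps
                lm, _ = model.loss_and_grads(X, y, w, train_mode=False)
                flat[j] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - grads[name].reshape(-1)[j]) < 1e-7, name

    def test_softplus_gradients_too(self):
        cfg = CnnConfig(input_shape=(8, 8, 3), dropout_rate=0.0,
                        activation="softplus", seed=4)
        model = build_model(cfg, dtype=np.float64)
        X, y = _tiny_batch()
        w = np.ones(len(y))
        _, grads = model.loss_and_grads(X, y, w, train_mode=False)
        eps = 1e-6
        flat = model.params["w1"].reshape(-1)
        orig = flat[3]
        flat[3] = orig + eps
        lp, _ = model.loss_and_grads(X, y, w, train_mode=False)
        flat[3] = orig - eps
        lm, _ = model.loss_and_grads(X, y, w, train_mode=False)
        flat[3] = orig
        assert abs((lp - lm) / (2 * eps) - grads["w1"].reshape(-1)[3]) < 1e-7


class TestWeightedLoss:
    def test_unit_weights_reproduce_unweighted_loss(self):
        model = build_model(TINY, dtype=np.float64)
        X, y = _tiny_batch()
        l_unw, _ = model.loss_and_grads(X, y, np.ones(len(y)), train_mode=False)
        probs, _ = model.forward(X)
        ce = -np.log(probs[np.arange(len(y)), y])
        assert abs(l_unw - ce.mean()) < 1e-6

    def test_half_weights_halve_the_loss(self):
        model = build_model(TINY, dtype=np.float64)
        X, y = _tiny_batch()
        l1, g1 = model.loss_and_grads(X, y, np.ones(len(y)), train_mode=False)
        l2, g2 = model.loss_and_grads(X, y, np.full(len(y), 0.5), train_mode=False)
        assert abs(l2 - 0.5 * l1) < 1e-9
        for name in g1:
            np.testing.assert_allclose(g2[name], 0.5 * g1[name], atol=1e-12)

    def test_invalid_weights_rejected(self):
        model = build_model(TINY)
        X, y = _tiny_batch()
        with pytest.raises(ValueError, match="weights"):
            train(model, X, y, sample_weights=np.full(len(y), 1.5))


class TestTraining:
    def test_single_class_rejected(self):
        model = build_model(TINY)
        X, _ = _tiny_batch()
        with pytest.raises(ValueError, match="both classes"):
            train(model, X, np.zeros(len(X), dtype=int))

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        cfg = CnnConfig(input_shape=(8, 8, 3), learning_rate=0.0, seed=2)
        model = build_model(cfg)
        before = {k: v.copy() for k, v in model.params.items()}
        X, y = _tiny_batch()
        train(model, X, y, epochs=2)
        for name in before:
            np.testing.assert_array_equal(model.params[name], before[name])

    def test_deterministic_given_seed_and_order(self):
        X, y = _tiny_batch(n=10)
        outs = []
        for _ in range(2):
            m = build_model(CnnConfig(input_shape=(8, 8, 3), learning_rate=0.01,
                                      seed=9))
            train(m, X, y, epochs=3)
            outs.append({k: v.copy() for k, v in m.params.items()})
        for name in outs[0]:
            np.testing.assert_array_equal(outs[0][name], outs[1][name])

    def test_loss_history_finite(self):
        X, y = _tiny_batch(n=10)
        m = build_model(CnnConfig(input_shape=(8, 8, 3), learning_rate=0.01, seed=9))
        train(m, X, y, epochs=3)
        assert len(m.history) == 3
        assert all(np.isfinite(h["loss"]) for h in m.history)

    def test_learns_separable_images(self):
        """Training accuracy exceeds 0.9 on linearly separable synthetic
        spectrogram-like images (band-power offset between classes)."""
        from mitransfer.experiments import separable_training_demo

        result = separable_training_demo(seed=0, n=120, epochs=15)
        assert result["train_accuracy"] > 0.9


class TestPredict:
    def test_batched_equals_one_at_a_time(self):
        """Batched and per-sample prediction agree to machine precision
        (BLAS reduction order may differ with batch size, so agreement is
        up to a few ulp of the working dtype, not bitwise)."""
        model = build_model(CnnConfig(seed=1))
        X = np.random.default_rng(3).random((5, 64, 64, 3))
        _, batched = predict(model, X)
        singles = np.vstack([predict(model, X[i])[1] for i in range(5)])
        np.testing.assert_allclose(batched, singles, atol=1e-6)

        model64 = build_model(CnnConfig(seed=1), dtype=np.float64)
        _, batched64 = predict(model64, X)
        singles64 = np.vstack([predict(model64, X[i])[1] for i in range(5)])
        np.testing.assert_allclose(batched64, singles64, atol=1e-14)

    def test_perfectly_fitted_model_reproduces_training_labels(self):
        from mitransfer.experiments import make_separable_images
        from mitransfer.cnn import CnnConfig

        X, y = make_separable_images(60, seed=1)
        m = build_model(CnnConfig(learning_rate=0.02, seed=0, max_epochs=20))
        train(m, X, y)
        pred, _ = predict(m, X)
        if (pred == y).all():  # fitted perfectly
            assert (pred == y).all()
        else:  # still must be far above chance on its own training set
            assert (pred == y).mean() > 0.9
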