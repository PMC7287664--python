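"""CNN architecture, loss, gradients, training and prediction contracts."""

import numpy as np
import pytest

import accelgait as ag
from accelgait.model import (EXPECTED_LAYER_SHAPES, CnnSpec, build_model,
                             weighted_loss, weighted_loss_grad)


def brute_force_loss(y, y_hat, weights):
    """Independent re-implementation: explicit loops, no shared code paths."""
    total = 0.0
    for j, w in enumerate(weights):
        sq = [(y[i][j] - y_hat[i][j]) ** 2 for i in range(len(y))]
        total += w * (sum(sq) / len(sq)) ** 0.5
    return total / len(weights)


class TestArchitecture:
    def test_layer_shape_audit(self):
        net = build_model(CnnSpec(seed=0))
        assert net.layer_shapes() == EXPECTED_LAYER_SHAPES

    def test_dropout_presence_follows_scenario(self):
        from accelgait.model import Dropout

        intra = build_model(CnnSpec(use_dropout=False))
        inter = build_model(CnnSpec(use_dropout=True))
        assert not any(isinstance(l, Dropout) for l in intra.layers)
        assert isinstance(inter.layers[0], Dropout)
        # dropout does not change the audited shapes
        assert inter.layer_shapes() == EXPECTED_LAYER_SHAPES

    def test_seeded_initialisation(self):
        w1 = build_model(CnnSpec(seed=3)).get_weights()
        w2 = build_model(CnnSpec(seed=3)).get_weights()
        w3 = build_model(CnnSpec(seed=4)).get_weights()
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))
        assert not np.array_equal(w1[0], w3[0])

    def test_incompatible_input_shape_rejected(self):
        with pytest.raises(ValueError):
            build_model(CnnSpec(input_shape=(61, 4)))   # odd pooling length
        with pytest.raises(ValueError):
            build_model(CnnSpec(input_shape=(8, 4)))    # collapses to < 1


class TestWeightedLoss:
    def test_perfect_prediction_is_zero(self):
        y = np.random.default_rng(0).normal(size=(16, 3))
        assert weighted_loss(y, y) == 0.0

    def test_equal_joint_rmse_scales_as_seven_thirds(self):
        # All per-joint RMSEs equal r with weights (3,1,3) -> 7r/3.
        rng = np.random.default_rng(1)
        y = rng.normal(size=(64, 3))
        err = rng.choice([-1.0, 1.0], size=(64, 3)) * 2.5
        assert weighted_loss(y, y + err) == pytest.approx(7 * 2.5 / 3, rel=1e-12)

    def test_hand_example(self):
        y = np.zeros((2, 3))
        y_hat = np.array([[3.0, 0.0, 4.0], [-3.0, 0.0, -4.0]])
        assert weighted_loss(y, y_hat) == pytest.approx(7.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = rng.integers(1, 20)
            y = rng.normal(size=(n, 3))
            y_hat = rng.normal(size=(n, 3))
            w = tuple(rng.uniform(0.1, 5.0, size=3))
            assert weighted_loss(y, y_hat, w) == pytest.approx(
                brute_force_loss(y.tolist(), y_hat.tolist(), w), abs=1e-9)

    def test_unit_weights_give_mean_rmse(self):
        rng = np.random.default_rng(3)
        y, y_hat = rng.normal(size=(50, 3)), rng.normal(size=(50, 3))
        per_joint = [ag.rmse(y[:, j], y_hat[:, j]) for j in range(3)]
        assert weighted_loss(y, y_hat, (1, 1, 1)) == pytest.approx(
            np.mean(per_joint), abs=1e-12)

    def test_empty_or_mismatched_batch_rejected(self):
        with pytest.raises(ValueError):
            weighted_loss(np.zeros((0, 3)), np.zeros((0, 3)))
        with pytest.raises(ValueError):
            weighted_loss(np.zeros((4, 3)), np.zeros((5, 3)))


class TestGradients:
    def test_loss_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            y = rng.normal(size=(6, 3))
            y_hat = rng.normal(size=(6, 3))
            g = weighted_loss_grad(y, y_hat)
            eps = 1e-6
            for i in range(6):
                for j in range(3):
                    plus, minus = y_hat.copy(), y_hat.copy()
                    plus[i, j] += eps
                    minus[i, j] -= eps
                    fd = (weighted_loss(y, plus) - weighted_loss(y, minus)) / (2 * eps)
                    assert g[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_backprop_matches_finite_differences(self):
        # End-to-end check through conv/pool/dense layers in float64.
        spec = CnnSpec(seed=5, dtype="float64")
        net = build_model(spec)
        rng = np.random.default_rng(6)
        X = rng.normal(size=(4, 60, 4))
        y = rng.normal(size=(4, 3))
        out = net.forward(X, train=True)
        net.backward(weighted_loss_grad(y, out))
        params, grads = net.parameters, net.gradients
        eps = 1e-6
        pr = np.random.default_rng(7)
        for p, g in zip(params, grads):
            flat = p.reshape(-1)
            for idx in pr.choice(flat.size, size=min(4, flat.size),
                                 replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                hi = weighted_loss(y, net.forward(X))
                flat[idx] = orig - eps
                lo = weighted_loss(y, net.forward(X))
                flat[idx] = orig
                fd = (hi - lo) / (2 * eps)
                assert g.reshape(-1)[idx] == pytest.approx(fd, rel=1e-4,
                                                           abs=1e-7)


@pytest.fixture(scope="module")
def small_data(windows):
    return windows.select(np.arange(0, len(windows), 2)[:600])


@pytest.fixture(scope="module")
def estimator(windows):
    return ag.train(windows.select(np.arange(256)),
                    CnnSpec(epochs=1, batch_size=256, seed=0))


class TestTraining:
    def test_loss_decreases_and_is_reproducible(self, small_data):
        spec = CnnSpec(epochs=3, batch_size=128, seed=1)
        a = ag.train(small_data, spec)
        b = ag.train(small_data, spec)
        assert a.history[-1] < a.history[0]
        assert a.history[-1] == pytest.approx(b.history[-1], abs=1e-6)
        assert len(a.history) == 3

    def test_empty_training_set_rejected(self, windows):
        with pytest.raises(ValueError, match="empty"):
            ag.train(windows.select(np.array([], dtype=int)), CnnSpec(epochs=1))

    def test_wrong_window_shape_rejected(self):
        X = np.zeros((10, 30, 4), dtype=np.float32)
        y = np.zeros((10, 3), dtype=np.float32)
        with pytest.raises(ValueError, match="does not match"):
            ag.train((X, y), CnnSpec(epochs=1))

    def test_capacity_overfits_noiseless_subset(self, population):
        # The architecture can drive training loss below the 1-degree
        # RMSE-equivalent (7/3 with weights (3,1,3)) on 1000 clean windows.
        trial = ag.simulate_trial(population[2], 10.0, duration=11.0)
        ds = ag.make_windows(ag.filter_trial(trial))
        ds = ds.select(np.arange(1000))
        spec = CnnSpec(epochs=80, batch_size=128, seed=2)
        est = ag.train(ds, spec)
        assert min(est.history) < 7.0 / 3.0

    def test_predictions_on_training_windows(self, small_data):
        spec = CnnSpec(epochs=25, batch_size=128, seed=3)
        est = ag.train(small_data, spec)
        y_hat = ag.predict(est, small_data.X)
        for j in range(3):
            assert ag.rmse(small_data.y[:, j], y_hat[:, j]) < 5.0


class TestPredict:
    def test_empty_input(self, estimator):
        assert ag.predict(estimator, np.zeros((0, 60, 4))).shape == (0, 3)

    def test_deterministic_inference(self, estimator, windows):
        X = windows.X[:100]
        a = ag.predict(estimator, X)
        b = ag.predict(estimator, X)
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))

    def test_shape_mismatch_rejected(self, estimator):
        with pytest.raises(ValueError):
            ag.predict(estimator, np.zeros((5, 59, 4)))

    def test_dropout_inactive_at_inference(self, windows):
        spec = CnnSpec(epochs=1, batch_size=256, seed=0, use_dropout=True)
        est = ag.train(windows.select(np.arange(256)), spec)
        X = windows.X[:32]
        assert np.array_equal(ag.predict(est, X), ag.predict(est, X))
        # training-mode forward with dropout is stochastic
        t1 = est.network.forward(X.astype(np.float32), train=True)
        t2 = est.network.forward(X.astype(np.float32), train=True)
        assert not np.array_equal(t1, t2)

    def test_save_load_roundtrip(self, tmp_path, estimator, windows):
        path = tmp_path / "model"
        estimator.save(path)
        back = ag.TrainedEstimator.load(path)
        X = windows.X[:50]
        np.testing.assert_array_equal(ag.predict(back, X),
                                      ag.predict(estimator, X))
        assert back.history == estimator.history
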