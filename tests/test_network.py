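"""Loss, schedule, augmentation, model assembly and the training loop."""

import math

import numpy as np
import pytest

from qtremor import network as nw


class TestCrossEntropy:
    def test_perfect_predictions_give_zero(self):
        y = nw.one_hot(np.array([0, 1, 2, 3]))
        assert nw.cross_entropy(y, y) <= 1e-10

    def test_uniform_predictions_give_log4(self):
        y = nw.one_hot(np.array([0, 1, 2, 3]))
        p = np.full((4, 4), 0.25)
        assert nw.cross_entropy(y, p) == pytest.approx(math.log(4), abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        y = nw.one_hot(rng.integers(0, 4, size=20))
        p = rng.dirichlet(np.ones(4), size=20)
        total = 0.0
        for i in range(20):
            for c in range(4):
                if y[i, c]:
                    total -= math.log(max(p[i, c], 1e-12))
        assert nw.cross_entropy(y, p) == pytest.approx(total / 20, abs=1e-12)

    def test_rejects_shape_mismatch_and_bad_rows(self):
        y = nw.one_hot(np.array([0, 1]))
        with pytest.raises(ValueError):
            nw.cross_entropy(y, np.ones((3, 4)) / 4)
        with pytest.raises(ValueError):
            nw.cross_entropy(y, np.full((2, 4), 0.3))


class TestPolynomialLR:
    def test_endpoints_and_midpoint(self):
        cfg = nw.TrainConfig(lr0=1e-3, end_lr=1e-5, power=1.0, horizon=100)
        assert nw.polynomial_lr(0, cfg) == pytest.approx(1e-3)
        assert nw.polynomial_lr(100, cfg) == pytest.approx(1e-5)
        assert nw.polynomial_lr(50, cfg) == pytest.approx((1e-3 + 1e-5) / 2)

    def test_clamps_past_horizon(self):
        cfg = nw.TrainConfig(lr0=1e-3, end_lr=1e-5, horizon=10)
        assert nw.polynomial_lr(25, cfg) == pytest.approx(1e-5)


class TestLabelNoise:
    def test_rate_zero_is_identity(self, rng):
        y = rng.integers(0, 4, size=100)
        assert np.array_equal(nw.add_label_noise(y, 0.0, seed=1), y)

    def test_rate_one_flips_everything(self, rng):
        y = rng.integers(0, 4, size=200)
        noisy = nw.add_label_noise(y, 1.0, seed=2)
        assert np.all(noisy != y)
        assert np.all((noisy >= 0) & (noisy < 4))

    def test_flip_fraction_within_binomial_bound(self):
        y = np.zeros(1000, dtype=int)
        rate = 0.2
        noisy = nw.add_label_noise(y, rate, seed=3)
        frac = (noisy != y).mean()
        assert abs(frac - rate) <= 4 * math.sqrt(rate * (1 - rate) / 1000)

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            nw.add_label_noise(np.array([0, 7]), 0.1)


class TestModelAssembly:
    def test_classical_shape_chain(self):
        # printed chain: conv 32x215x16, pool 16x107x16
        spec = nw.ModelSpec(kind="classical", input_shape=(32, 215, 1))
        net = nw.build_model(spec, seed=0)
        x = np.zeros((2, 32, 215, 1))
        h = x
        shapes = []
        for layer in net.layers:
            h = layer.forward(h, train=False)
            shapes.append((type(layer).__name__, h.shape[1:]))
        conv_shapes = [s for name, s in shapes if name == "Conv2D"]
        assert conv_shapes[0] == (32, 215, 16)
        pool_shapes = [s for name, s in shapes if name == "MaxPool2"]
        assert pool_shapes[0] == (16, 107, 16)
        assert conv_shapes[1] == (16, 107, 16)
        flat = [s for name, s in shapes if name == "Flatten"][0]
        assert flat == (16 * 107 * 16,)  # 27392, built from the shape chain
        assert shapes[-1][1] == (4,)

    def test_hybrid_head_outputs_probabilities(self, rng):
        spec = nw.ModelSpec(kind="hybrid", input_shape=(16, 20, 4))
        net = nw.build_model(spec, seed=0)
        p = net.forward(rng.random((3, 16, 20, 4)), train=False)
        assert p.shape == (3, 4)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= 0)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            nw.build_model(nw.ModelSpec(kind="hybrid", input_shape=(2, 2, 1)))

    def test_gradients_match_finite_differences(self, rng):
        # one spot-check per parameter tensor of a tiny classical net
        spec = nw.ModelSpec(kind="classical", input_shape=(8, 10, 1), dense_width=5)
        net = nw.build_model(spec, seed=0)
        x = rng.random((3, 8, 10, 1))
        y = nw.one_hot(np.array([0, 2, 3]))

        def loss():
            return nw.cross_entropy(y, net.forward(x, train=False))

        net.forward(x, train=False)
        net.backward(y)
        for obj, name in net.parameters():
            g = obj.grads[name]
            w = obj.params[name]
            idx = tuple(rng.integers(0, s) for s in w.shape)
            eps = 1e-5
            w[idx] += eps
            lp = loss()
            w[idx] -= 2 * eps
            lm = loss()
            w[idx] += eps
            fd = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(fd, abs=1e-6, rel=1e-4)


class TestEvaluate:
    class _OneHotModel:
        def __init__(self, y):
            self._p = nw.one_hot(y)

        def predict_proba(self, x):
            return self._p

    class _UniformModel:
        def predict_proba(self, x):
            return np.full((x.shape[0], 4), 0.25)

    def test_oracle_model_scores_one(self):
        y = np.array([0, 1, 2, 3, 1])
        loss, acc = nw.evaluate(self._OneHotModel(y), np.zeros((5, 1)), y)
        assert acc == 1.0 and loss <= 1e-10

    def test_uniform_predictor_tie_breaks_to_class_zero(self):
        y = np.array([0, 1, 2, 3])
        loss, acc = nw.evaluate(self._UniformModel(), np.zeros((4, 1)), y)
        assert acc == 0.25  # argmax ties resolve to class 0
        assert loss == pytest.approx(math.log(4), abs=1e-12)

    def test_loss_equals_cross_entropy_oracle(self, rng):
        y = rng.integers(0, 4, size=6)
        model = self._OneHotModel(y)
        loss, _ = nw.evaluate(model, np.zeros((6, 1)), y)
        assert loss == pytest.approx(nw.cross_entropy(nw.one_hot(y),
                                                      model.predict_proba(None)),
                                     abs=1e-15)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            nw.evaluate(self._UniformModel(), np.zeros((0, 1)), np.array([], dtype=int))


def _toy_arrays(rng, n=24, shape=(8, 12)):
    """Tiny 4-class dataset separable by overall contrast."""
    scales = [0.02, 0.2, 0.5, 0.9]
    x, y = [], []
    for i in range(n):
        c = i % 4
        x.append(0.5 + scales[c] * 0.5 * np.sin(
            np.linspace(0, 12, shape[0] * shape[1]) + rng.uniform(0, 6)
        ).reshape(shape) + rng.normal(0, 0.01, size=shape))
        y.append(c)
    x = np.clip(np.stack(x), 0, 1)[..., None]
    y = np.array(y)
    return nw.ArrayDataset(x, y, x[:8], y[:8], x[:8], y[:8])


class TestTraining:
    def test_loss_decreases_on_separable_data(self, rng):
        ds = _toy_arrays(rng)
        spec = nw.ModelSpec(kind="hybrid", input_shape=ds.x_train.shape[1:])
        net = nw.build_model(spec, seed=0)
        res = nw.train(net, ds, nw.TrainConfig(epochs=25, label_noise=0.0, seed=0))
        assert len(res.epoch_train_loss) == 25
        assert res.epoch_train_loss[-1] < res.epoch_train_loss[0]

    def test_same_seed_gives_identical_traces(self, rng):
        ds = _toy_arrays(rng, n=16)
        out = []
        for _ in range(2):
            spec = nw.ModelSpec(kind="classical", input_shape=ds.x_train.shape[1:],
                                dense_width=8)
            net = nw.build_model(spec, seed=5)
            res = nw.train(net, ds, nw.TrainConfig(epochs=3, seed=5))
            out.append(res.epoch_train_loss)
        assert out[0] == out[1]

    def test_literal_head_freezes_the_whole_network(self, rng):
        # the flat printed circuit backpropagates exactly zero, so no
        # parameter moves during training
        ds = _toy_arrays(rng, n=16)
        spec = nw.ModelSpec(kind="hybrid", input_shape=ds.x_train.shape[1:],
                            head="quantclass", head_mode="literal")
        net = nw.build_model(spec, seed=2)
        before = [obj.params[name].copy() for obj, name in net.parameters()]
        res = nw.train(net, ds, nw.TrainConfig(epochs=3, seed=2))
        after = [obj.params[name] for obj, name in net.parameters()]
        for b, a in zip(before, after):
            # the gradient is zero analytically; Adam turns float rounding of
            # the flat distribution into parameter dust of ~1e-12 per step
            assert np.allclose(b, a, atol=1e-8)
        assert res.epoch_train_loss[-1] == pytest.approx(math.log(4), abs=1e-9)

    def test_fixed_epoch_contract(self, rng):
        ds = _toy_arrays(rng, n=12)
        spec = nw.ModelSpec(kind="hybrid", input_shape=ds.x_train.shape[1:])
        net = nw.build_model(spec, seed=1)
        res = nw.train(net, ds, nw.TrainConfig(epochs=7, seed=1))
        assert len(res.epoch_train_loss) == 7

    def test_empty_split_rejected(self, rng):
        ds = _toy_arrays(rng, n=12)
        bad = nw.ArrayDataset(ds.x_train, ds.y_train, ds.x_val[:0], ds.y_val[:0],
                              ds.x_test, ds.y_test)
        spec = nw.ModelSpec(kind="hybrid", input_shape=ds.x_train.shape[1:])
        net = nw.build_model(spec, seed=1)
        with pytest.raises(ValueError):
            nw.train(net, bad, nw.TrainConfig(epochs=1))
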