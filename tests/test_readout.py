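"""Readout heads: linear softmax, tiny CNN, CAM, conductance quantization."""

import numpy as np
import pytest

from fibrc.readout import (LabeledStateSet, LinearReadout, cam, predict,
                           quantize_weights, softmax_loss_grad, train_cnn,
                           train_linear, train_val_split)
from fibrc.reservoir import ReservoirStateVector


def make_blobs(n_per_class=20, n_classes=2, d=12, sep=6.0, seed=0,
               layout=None):
    """Linearly separable Gaussian clusters as mock reservoir states."""
    rng = np.random.default_rng(seed)
    layout = layout or (1, d)
    states, labels = [], []
    for c in range(n_classes):
        centre = np.zeros(d)
        centre[c % d] = sep
        for _ in range(n_per_class):
            v = centre + rng.standard_normal(d)
            states.append(ReservoirStateVector(v, layout))
            labels.append(c)
    mode = {2: "snore2", 3: "stage3", 6: "joint6"}[n_classes]
    return LabeledStateSet(states, np.array(labels), mode)


class TestTrainLinear:
    def test_separable_clusters_reach_full_training_accuracy(self):
        model = train_linear(make_blobs(), l2=0.1)
        assert model.train_accuracy == 1.0

    def test_huge_l2_shrinks_weights_to_class_priors(self):
        data = make_blobs(n_per_class=10, n_classes=3, d=6)
        # unbalance the classes so priors are informative
        keep = np.r_[np.arange(10), np.arange(10, 16), np.arange(20, 23)]
        data = data.subset(keep)
        model = train_linear(data, l2=1e8)
        assert np.abs(model.W).max() < 1e-4
        _, scores = predict(model, data.states)
        priors = np.bincount(data.labels, minlength=3) / data.labels.size
        np.testing.assert_allclose(scores[0], priors, atol=1e-3)

    def test_gradient_norm_small_at_optimum(self):
        data = make_blobs(n_per_class=15, n_classes=3, d=8, sep=2.0)
        model = train_linear(data, l2=1.0)
        Xs = model.transform(data.states)
        _, gW, gb = softmax_loss_grad(model.W, model.b, Xs, data.labels, 1.0)
        assert np.sqrt((gW ** 2).sum() + (gb ** 2).sum()) < 1e-5

    def test_analytic_gradient_matches_finite_differences(self, rng):
        # independent check of the objective the optimizer minimizes
        X = rng.standard_normal((12, 4))
        y = rng.integers(0, 3, 12)
        W = rng.standard_normal((4, 3)) * 0.3
        b = rng.standard_normal(3) * 0.1
        loss, gW, gb = softmax_loss_grad(W, b, X, y, l2=0.5)
        eps = 1e-6
        for idx in [(0, 0), (2, 1), (3, 2)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            lp = softmax_loss_grad(Wp, b, X, y, 0.5)[0]
            lm = softmax_loss_grad(Wm, b, X, y, 0.5)[0]
            assert gW[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)

    def test_single_class_rejected(self):
        data = make_blobs(n_per_class=8, n_classes=2)
        with pytest.raises(ValueError):
            train_linear(data.subset(np.arange(8)))

    def test_label_permutation_permutes_scores(self):
        data = make_blobs(n_per_class=12, n_classes=3, d=6, sep=3.0)
        perm = np.array([2, 0, 1])
        permuted = LabeledStateSet(data.states, perm[data.labels], "stage3")
        m1 = train_linear(data, l2=1.0)
        m2 = train_linear(permuted, l2=1.0)
        _, s1 = predict(m1, data.states)
        _, s2 = predict(m2, data.states)
        np.testing.assert_allclose(s2[:, perm], s1, atol=1e-4)


class TestTrainCNN:
    def _grid_blobs(self, n_per_class=12, n_classes=3, shape=(10, 8),
                    seed=0):
        rng = np.random.default_rng(seed)
        states, labels = [], []
        for c in range(n_classes):
            for _ in range(n_per_class):
                g = rng.standard_normal(shape)
                g[c:c + 3, :] += 4.0
                states.append(ReservoirStateVector(g.ravel(), shape))
                labels.append(c)
        return LabeledStateSet(states, np.array(labels), "stage3")

    def test_constant_inputs_give_majority_class_accuracy(self):
        shape = (10, 8)
        states = [ReservoirStateVector(np.ones(80), shape) for _ in range(30)]
        labels = np.array([0] * 18 + [1] * 6 + [2] * 6)
        data = LabeledStateSet(states, labels, "stage3")
        model = train_cnn(data, epochs=60, lr=0.1, seed=0)
        assert model.train_accuracy == pytest.approx(18 / 30)

    def test_learns_separable_grids(self):
        data = self._grid_blobs()
        model = train_cnn(data, epochs=150, lr=0.3, seed=1)
        assert model.train_accuracy >= 0.9

    def test_loss_non_increasing_with_small_step(self):
        data = self._grid_blobs(n_per_class=8)
        model = train_cnn(data, epochs=40, lr=0.01, seed=2)
        curve = np.array(model.training_curve)
        assert np.all(np.diff(curve) <= 1e-10)

    def test_seed_reproducibility(self):
        data = self._grid_blobs(n_per_class=6)
        m1 = train_cnn(data, epochs=20, lr=0.1, seed=7)
        m2 = train_cnn(data, epochs=20, lr=0.1, seed=7)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_small_grid_falls_back_to_single_conv(self):
        rng = np.random.default_rng(0)
        shape = (4, 6)
        states = [ReservoirStateVector(rng.standard_normal(24), shape)
                  for _ in range(12)]
        data = LabeledStateSet(states, np.array([0, 1] * 6), "snore2")
        model = train_cnn(data, epochs=10, lr=0.1, seed=0)
        assert model.arch == "single"
        assert "k2" not in model.params


class TestPredict:
    def test_identity_on_separable_training_data(self):
        data = make_blobs()
        model = train_linear(data, l2=0.1)
        yhat, _ = predict(model, data.states)
        np.testing.assert_array_equal(yhat, data.labels)

    def test_scores_sum_to_one(self):
        data = make_blobs(n_classes=3)
        model = train_linear(data, l2=1.0)
        _, scores = predict(model, data.states)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-12)

    def test_batch_equals_per_sample(self):
        data = make_blobs(n_per_class=5)
        model = train_linear(data, l2=1.0)
        _, batch = predict(model, data.states)
        singles = np.vstack([predict(model, [s])[1] for s in data.states])
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        model = train_linear(make_blobs(d=12), l2=1.0)
        with pytest.raises(ValueError):
            model.logits(np.ones((2, 5)))


class TestCAM:
    def _identity_model(self, d=8, n_classes=2, layout=(2, 4), seed=0):
        rng = np.random.default_rng(seed)
        return LinearReadout("linear", rng.standard_normal((d, n_classes)),
                             rng.standard_normal(n_classes), np.zeros(d),
                             np.ones(d), 1.0, ("a", "b"), layout)

    def test_zero_state_gives_zero_cam(self):
        model = self._identity_model()
        maps = cam(model, ReservoirStateVector(np.zeros(8), (2, 4)))
        np.testing.assert_array_equal(maps, 0.0)

    def test_cam_sums_to_logit_minus_bias(self, rng):
        model = self._identity_model(seed=3)
        state = ReservoirStateVector(rng.standard_normal(8), (2, 4))
        maps = cam(model, state)
        logits = model.logits([state])[0]
        for c in range(2):
            assert maps[c].sum() + model.b[c] == pytest.approx(
                logits[c], abs=1e-9)

    def test_cam_argmax_is_largest_weight_state_product(self, rng):
        model = self._identity_model(seed=5)
        x = rng.standard_normal(8)
        maps = cam(model, ReservoirStateVector(x, (2, 4)))
        for c in range(2):
            assert np.argmax(np.abs(maps[c])) == np.argmax(
                np.abs(model.W[:, c] * x))

    def test_cnn_cam_has_grid_shape(self):
        rng = np.random.default_rng(0)
        shape = (10, 8)
        states = [ReservoirStateVector(rng.standard_normal(80), shape)
                  for _ in range(12)]
        data = LabeledStateSet(states, np.array([0, 1] * 6), "snore2")
        model = train_cnn(data, epochs=5, lr=0.1, seed=0)
        maps = cam(model, states[0])
        assert maps.shape == (2, 10, 8)


class TestQuantization:
    def test_weights_on_grid_are_unchanged(self):
        data = make_blobs(n_per_class=10)
        model = train_linear(data, l2=1.0)
        delta = np.abs(model.W).max() / 15
        model.W[...] = np.round(model.W / delta) * delta
        qm = quantize_weights(model, 16)
        np.testing.assert_allclose(qm.quantized["W"], model.W, atol=1e-15)

    def test_error_at_most_half_level_spacing(self):
        model = train_linear(make_blobs(n_per_class=12, sep=3.0), l2=1.0)
        qm = quantize_weights(model, 16)
        spacing = np.abs(model.W).max() / 15
        assert np.abs(qm.quantized["W"] - model.W).max() <= spacing / 2 + 1e-15

    def test_quantized_weights_in_level_set(self):
        model = train_linear(make_blobs(n_per_class=12), l2=1.0)
        qm = quantize_weights(model, 16)
        levels = qm.level_values["W"]
        allowed = np.concatenate([-levels, levels])
        q = qm.quantized["W"].ravel()
        dist = np.min(np.abs(q[:, None] - allowed[None, :]), axis=1)
        assert dist.max() < 1e-12

    def test_accuracy_delta_recorded(self):
        data = make_blobs(n_per_class=15, n_classes=3, d=10, sep=4.0)
        tr, va = train_val_split(data, 0.2, seed=0)
        model = train_linear(tr, l2=1.0)
        qm = quantize_weights(model, 16, eval_data=va)
        assert qm.accuracy_delta is not None
        assert qm.accuracy_delta >= -0.05

    def test_too_few_levels_rejected(self):
        model = train_linear(make_blobs(), l2=1.0)
        with pytest.raises(ValueError):
            quantize_weights(model, 1)


class TestSplit:
    def test_split_is_stratified_and_disjoint(self):
        data = make_blobs(n_per_class=20, n_classes=3, d=6)
        tr, va = train_val_split(data, 0.2, seed=3)
        assert np.bincount(va.labels).tolist() == [4, 4, 4]
        assert tr.labels.size + va.labels.size == 60

    def test_split_seed_reproducible(self):
        data = make_blobs(n_per_class=10)
        a = train_val_split(data, 0.2, seed=5)[1].labels
        b = train_val_split(data, 0.2, seed=5)[1].labels
        np.testing.assert_array_equal(a, b)
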