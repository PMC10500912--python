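"""Dense head, losses, gradient correctness, parameter counting, training."""

import math

import numpy as np
import pytest

from quanvnet import classical_nn as nn
from quanvnet import data_synth, quanvolution as qv
from quanvnet.adaptive_optimizer import MomentumSGD


class TestLosses:
    def test_softmax_uniform(self):
        np.testing.assert_allclose(nn.softmax(np.zeros(4)), 0.25)

    def test_softmax_shift_invariance(self, rng):
        z = rng.normal(size=6)
        np.testing.assert_allclose(nn.softmax(z), nn.softmax(z + 123.4),
                                   atol=1e-12)

    def test_softmax_log_odds(self):
        np.testing.assert_allclose(
            nn.softmax(np.log([1.0, 3.0])), [0.25, 0.75], atol=1e-12
        )

    def test_softmax_rows_sum_to_one(self, rng):
        probs = nn.softmax(rng.normal(size=(5, 4)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_squared_error(self):
        assert nn.squared_error(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 0
        assert nn.squared_error(np.array([1.0, 0.0]),
                                np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_squared_error_non_negative(self, rng):
        t, o = rng.normal(size=4), rng.normal(size=4)
        assert nn.squared_error(t, o) >= 0.0

    def test_cross_entropy_values(self):
        assert nn.cross_entropy(0, np.array([1.0, 0.0])) == pytest.approx(0.0)
        assert nn.cross_entropy(2, np.full(4, 0.25)) == pytest.approx(
            math.log(4.0)
        )

    def test_cross_entropy_monotone_in_true_prob(self):
        losses = [
            nn.cross_entropy(0, np.array([p, 1.0 - p]))
            for p in (0.1, 0.3, 0.6, 0.9)
        ]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_cross_entropy_bad_index(self):
        with pytest.raises(IndexError):
            nn.cross_entropy(9, np.full(4, 0.25))


class TestParameterCounting:
    def test_dense_layer_counts(self):
        assert nn.DenseSpec(4, 128).num_parameters == 640
        assert nn.DenseSpec(128, 64).num_parameters == 8256
        assert nn.DenseSpec(64, 4).num_parameters == 260

    def test_ga_selected_hqcnn_total(self):
        assert nn.count_trainable_parameters(nn.ga_selected_hqcnn()) == 9160

    def test_frozen_kernel_drops_four(self):
        arch = nn.ga_selected_hqcnn(trainable_kernel=False)
        assert nn.count_trainable_parameters(arch) == 9156

    def test_additive_over_concatenation(self):
        a = nn.ArchitectureSpec([nn.DenseSpec(4, 8), nn.DenseSpec(8, 2)])
        b = nn.ArchitectureSpec([nn.DenseSpec(3, 5)])
        combined = nn.ArchitectureSpec(a.layers + [nn.FlattenSpec()] + b.layers)
        assert nn.count_trainable_parameters(combined) == (
            nn.count_trainable_parameters(a) + nn.count_trainable_parameters(b)
        )

    def test_conv_standard_counting(self):
        # (k*k*cin + 1) * cout
        assert nn.Conv2DSpec(1, 32, 2).num_parameters == 160
        assert nn.Conv2DSpec(32, 64, 2).num_parameters == 8256

    def test_inconsistent_dense_chain_rejected(self):
        with pytest.raises(ValueError):
            nn.ArchitectureSpec([nn.DenseSpec(4, 8), nn.DenseSpec(9, 2)])


class TestForward:
    def test_zero_weights_softmax_uniform(self):
        model = nn.Model(nn.ArchitectureSpec([nn.DenseSpec(3, 4, "softmax")]),
                         seed=0)
        model.layers[0].weights[:] = 0.0
        out = model.forward(np.ones((2, 3)))
        np.testing.assert_allclose(out, 0.25)

    def test_single_dense_matches_matrix_product(self, rng):
        model = nn.Model(nn.ArchitectureSpec([nn.DenseSpec(3, 2, "none")]),
                         seed=1)
        x = rng.normal(size=(4, 3))
        expected = x @ model.layers[0].weights + model.layers[0].bias
        np.testing.assert_allclose(model.forward(x), expected, atol=1e-12)

    def test_batch_rows(self, rng):
        model = nn.Model(nn.dense_head(6), seed=2)
        out = model.forward(rng.normal(size=(5, 6)))
        assert out.shape == (5, 4)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_dimension_mismatch(self):
        model = nn.Model(nn.dense_head(6), seed=0)
        with pytest.raises(ValueError):
            model.forward(np.ones((2, 7)))


def finite_difference_grads(model, x, y, eps=1e-6):
    grads = []
    for p in model.parameters():
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp = model.loss(model.forward(x), y)
            p[idx] = orig - eps
            lm = model.loss(model.forward(x), y)
            p[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
        grads.append(g)
    return grads


def relative_error(a, b):
    num = np.linalg.norm(a - b)
    den = max(np.linalg.norm(a) + np.linalg.norm(b), 1e-12)
    return num / den


class TestBackward:
    @pytest.mark.parametrize("loss", ["cross_entropy", "squared_error"])
    def test_gradcheck_dense_models(self, loss):
        """Analytic gradients vs central differences on 20 random models."""
        rng = np.random.default_rng(99)
        for trial in range(20):
            dims = [int(rng.integers(2, 6)) for _ in range(3)]
            arch = nn.ArchitectureSpec(
                [
                    nn.DenseSpec(dims[0], dims[1],
                                 ["tanh", "sigmoid", "relu"][trial % 3]),
                    nn.DenseSpec(dims[1], dims[2], "tanh"),
                    nn.DenseSpec(dims[2], 3, "softmax"),
                ]
            )
            model = nn.Model(arch, seed=trial, loss=loss)
            x = rng.normal(size=(4, dims[0]))
            y = rng.integers(0, 3, size=4)
            model.loss_and_gradients(x, y)
            analytic = model.gradients()
            numeric = finite_difference_grads(model, x, y)
            for a, g in zip(analytic, numeric):
                assert relative_error(a, g) < 1e-5

    def test_gradcheck_conv_model(self, rng):
        arch = nn.ArchitectureSpec(
            [
                nn.Conv2DSpec(1, 2, 2),
                nn.MaxPoolSpec(2),
                nn.FlattenSpec(),
                nn.DenseSpec(8, 3, "softmax"),
            ]
        )
        model = nn.Model(arch, seed=3)
        x = rng.normal(size=(2, 4, 4, 1))
        y = np.array([0, 2])
        model.loss_and_gradients(x, y)
        analytic = model.gradients()
        numeric = finite_difference_grads(model, x, y)
        for a, g in zip(analytic, numeric):
            assert relative_error(a, g) < 1e-5

    def test_quanv_parameter_shift_matches_finite_differences(self):
        """Kernel angles: parameter-shift gradients vs central differences."""
        rng = np.random.default_rng(11)
        arch = nn.ArchitectureSpec(
            [
                nn.QuanvSpec(trainable=True),
                nn.FlattenSpec(),
                nn.DenseSpec(4, 3, "softmax"),
            ]
        )
        model = nn.Model(arch, seed=5)
        x = rng.uniform(0, 1, size=(2, 3, 3))
        y = np.array([0, 1])
        model.loss_and_gradients(x, y)
        analytic = model.gradients()
        numeric = finite_difference_grads(model, x, y)
        for a, g in zip(analytic, numeric):
            assert relative_error(a, g) < 1e-5

    def test_gradients_vanish_at_perfect_fit(self):
        model = nn.Model(
            nn.ArchitectureSpec([nn.DenseSpec(2, 2, "softmax")]), seed=0
        )
        model.layers[0].weights[:] = np.array([[40.0, -40.0], [-40.0, 40.0]])
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([0, 1])
        model.loss_and_gradients(x, y)
        for g in model.gradients():
            assert np.max(np.abs(g)) < 1e-8


class TestTraining:
    def _features(self, dataset, seed=0):
        rng = np.random.default_rng(seed)
        kernel = qv.QuanvKernel.random(rng)
        return qv.extract_features(dataset.images, kernel,
                                   qv.default_pooling())

    def test_history_length(self, small_dataset):
        x = self._features(small_dataset)
        model = nn.Model(nn.dense_head(x.shape[1]), seed=0)
        history = nn.train(model, (x, small_dataset.labels), epochs=3, seed=0)
        assert len(history) == 3
        assert {"epoch", "train_loss", "eval_loss", "eval_accuracy", "lr",
                "momentum"} <= set(history.records[0])

    def test_reproducible_given_seed(self, small_dataset):
        x = self._features(small_dataset)
        runs = []
        for _ in range(2):
            model = nn.Model(nn.dense_head(x.shape[1]), seed=4)
            h = nn.train(model, (x, small_dataset.labels),
                         optimizer=MomentumSGD(), epochs=4, seed=4)
            runs.append(h.column("train_loss"))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_losses_finite_and_accuracy_improves(self, small_dataset):
        train_set, test_set = data_synth.split_train_test(small_dataset,
                                                          0.8, seed=0)
        rng = np.random.default_rng(0)
        kernel = qv.QuanvKernel.random(rng)
        pool = qv.default_pooling()
        xt = qv.extract_features(train_set.images, kernel, pool)
        xe = qv.extract_features(test_set.images, kernel, pool)
        model = nn.Model(nn.dense_head(xt.shape[1]), seed=0)
        _, acc_before = model.evaluate(xe, test_set.labels)
        history = nn.train(model, (xt, train_set.labels),
                           (xe, test_set.labels),
                           optimizer=MomentumSGD(), epochs=15, seed=0)
        assert np.all(np.isfinite(history.column("train_loss")))
        assert history.records[-1]["eval_accuracy"] > acc_before

    def test_empty_dataset_rejected(self):
        model = nn.Model(nn.dense_head(4), seed=0)
        with pytest.raises(ValueError):
            nn.train(model, (np.empty((0, 4)), np.empty(0, dtype=int)))

    def test_save_load_round_trip(self, tmp_path, rng):
        model = nn.Model(nn.dense_head(6), seed=1)
        x = rng.normal(size=(3, 6))
        expected = model.forward(x)
        model.save(tmp_path / "model.zip")
        fresh = nn.Model(nn.dense_head(6), seed=999)
        fresh.load(tmp_path / "model.zip")
        np.testing.assert_allclose(fresh.forward(x), expected)
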