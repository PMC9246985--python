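"""Network engine gradients, architecture contracts, and the two-part loss."""

import numpy as np
import pytest

from cestnet import nn
from cestnet.cs_net import (
    C_EPS,
    ChemicalShiftNetwork,
    ShiftPrediction,
    calibrate_k,
    confidence_from_sigma,
    loss_freq,
    loss_uncer,
    map_shift,
    sigma_from_confidence,
)
from cestnet.scenarios import ValidationError
from cestnet.tr_net import TransformationNetwork


def _numerical_grad(f, p, eps=1e-6):
    g = np.zeros_like(p)
    it = np.nditer(p, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = p[i]
        p[i] = old + eps
        f1 = f()
        p[i] = old - eps
        f2 = f()
        p[i] = old
        g[i] = (f1 - f2) / (2 * eps)
    return g


class TestEngineGradients:
    def test_composite_network_backprop(self):
        """Analytic gradients of every layer type match central differences."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 8, 2))
        model = nn.Sequential(
            [
                nn.Conv1D(2, 3, 3, 1, "tanh", rng),
                nn.GatedConvBlock(3, 3, 2, rng),
                nn.DenseConv(3, 2, 3, rng),
                nn.BiRNN(5, 3, rng),
                nn.AvgPool1D(2),
                nn.Flatten(),
                nn.Dense(4 * 6, 4, "relu", rng),
                nn.Dense(4, 2, None, rng),
                nn.Activation("sigmoid"),
            ]
        )
        t = rng.normal(size=(2, 2))

        def loss():
            return float(np.sum((model.forward(x) - t) ** 2))

        y = model.forward(x)
        model.backward(2 * (y - t))
        for p, g in zip(model.params, model.grads):
            ng = _numerical_grad(loss, p)
            np.testing.assert_allclose(g, ng, atol=1e-6 * max(1.0, np.abs(ng).max()))

    def test_adam_determinism(self):
        def run():
            rng = np.random.default_rng(1)
            layer = nn.Dense(3, 2, None, rng)
            opt = nn.Adam(layer.params)
            x = rng.normal(size=(4, 3))
            for _ in range(5):
                y = layer.forward(x)
                layer.backward(2 * y / y.size)
                opt.step(layer.grads, 1e-3)
            return layer.W.copy()

        np.testing.assert_array_equal(run(), run())


class TestLosses:
    def test_loss_freq_zero_iff_exact(self):
        assert loss_freq([0.2, 0.5, 0.9], [0.2, 0.5, 0.9], [0.1, 0.1, 0.1]) == 0.0
        assert loss_freq([0.3], [0.2], [0.1]) == pytest.approx(1.0)

    def test_loss_freq_homogeneity(self):
        f, t = [0.3, 0.6, 0.1], [0.25, 0.5, 0.2]
        s = np.array([0.05, 0.1, 0.2])
        assert loss_freq(f, t, 2 * s) == pytest.approx(loss_freq(f, t, s) / 4.0)

    def test_loss_freq_rejects_nonpositive_sigma(self):
        with pytest.raises(ValidationError):
            loss_freq([0.1], [0.2], [0.0])

    def test_loss_uncer_two_state_example(self):
        val = loss_uncer([0.01, 0.04, 1e6], [1, 1, 0])
        assert val == pytest.approx(1e-4 * (0.1 + 0.2))

    def test_loss_uncer_zero_sigma(self):
        assert loss_uncer([0.0, 0.0, 0.0], [1, 1, 1]) == 0.0

    def test_loss_uncer_three_state_dominates(self):
        s = [0.1, 0.2, 0.3]
        assert loss_uncer(s, [1, 1, 1]) >= loss_uncer(s, [1, 1, 0])

    def test_training_loss_matches_scalar_reference(self):
        """The vectorized batch loss equals a hand-written per-sample loop."""
        rng = np.random.default_rng(2)
        out = rng.uniform(0.05, 0.95, size=(6, 3, 2))
        f_true = rng.uniform(0, 1, size=(6, 3))
        ind = (rng.random((6, 3)) < 0.7).astype(float)
        lf, lu, _ = ChemicalShiftNetwork._loss_and_grad(out, f_true, ind)
        ref_lf = ref_lu = 0.0
        for b in range(6):
            for i in range(3):
                c = min(max(out[b, i, 1], C_EPS), 1 - C_EPS)
                sigma = 1.0 / c - 1.0
                ref_lf += (out[b, i, 0] - f_true[b, i]) ** 2 / sigma**2
                ref_lu += 1e-4 * ind[b, i] * np.sqrt(sigma)
        assert lf == pytest.approx(ref_lf / 6)
        assert lu == pytest.approx(ref_lu / 6)

    def test_loss_gradient_matches_numerics(self):
        rng = np.random.default_rng(3)
        out = rng.uniform(0.1, 0.9, size=(3, 3, 2))
        f_true = rng.uniform(0, 1, size=(3, 3))
        ind = np.ones((3, 3))
        _, _, g = ChemicalShiftNetwork._loss_and_grad(out, f_true, ind)

        def total():
            lf, lu, _ = ChemicalShiftNetwork._loss_and_grad(out, f_true, ind)
            return lf + lu

        ng = _numerical_grad(total, out, eps=1e-7)
        np.testing.assert_allclose(g, ng, rtol=1e-4, atol=1e-8)


class TestConfidenceMapping:
    def test_bijection_roundtrip(self):
        c = np.linspace(0.01, 0.99, 50)
        np.testing.assert_allclose(
            confidence_from_sigma(sigma_from_confidence(c)), c, atol=1e-12
        )

    def test_limits(self):
        assert sigma_from_confidence(1.0) == pytest.approx(0.0, abs=2e-6)
        assert sigma_from_confidence(0.001) > 100

    def test_calibrate_k(self):
        assert round(calibrate_k(3.4, 7.3e-5), 3) == 0.029
        assert calibrate_k(1.0, 1.0) == 1.0
        assert calibrate_k(6.8, 2.5e-5) == pytest.approx(2 * calibrate_k(3.4, 2.5e-5))
        with pytest.raises(ValidationError):
            calibrate_k(3.4, 0.0)

    def test_map_shift(self):
        assert map_shift(0.0, 6.6, 3.4) == pytest.approx(6.6)
        assert map_shift(1.0, 6.6, 3.4) == pytest.approx(10.0)
        assert map_shift(0.5, 6.6, 3.4) == pytest.approx(8.3)
        with pytest.raises(ValidationError):
            map_shift(1.2, 6.6, 3.4)

    def test_shift_prediction_container(self):
        pred = ShiftPrediction([0.5, 0.2, 0.5], [0.9, 0.5, 0.05], 6.6, 3.4, 0.01)
        assert pred.delta[0] == pytest.approx(8.3)
        assert pred.sigma[2] > pred.sigma[0]
        assert pred.passes().tolist() == [True, True, False]


class TestArchitectureContracts:
    def test_tr_input_output_shapes(self):
        model = TransformationNetwork(
            channels=6, dilations=(1,), rnn_units=4, epochs=0
        )
        rng = np.random.default_rng(4)
        X = rng.normal(size=(4, 260)) * 0.1
        model.fit(X, np.zeros((4, 128)))
        out = model.transform(X)
        assert out.shape == (4, 128)
        assert np.all(np.isfinite(out))

    def test_tr_frequency_head(self):
        model = TransformationNetwork(
            channels=6, dilations=(1,), rnn_units=4, epochs=0, head="freq"
        )
        X = np.random.default_rng(5).normal(size=(2, 260)) * 0.1
        model.fit(X, np.zeros((2, 128)))
        assert model.transform(X).shape == (2, 128)

    def test_tr_rejects_bad_input(self):
        model = TransformationNetwork(channels=6, dilations=(1,), rnn_units=4, epochs=0)
        model.fit(np.zeros((2, 260)), np.zeros((2, 128)))
        with pytest.raises(ValidationError):
            model.transform(np.zeros((2, 100)))
        bad = np.full((1, 260), np.nan)
        with pytest.raises(ValidationError):
            model.transform(bad)

    def test_cs_output_contract(self):
        model = ChemicalShiftNetwork(epochs=1, block_depth=1, n_blocks=1, growth=4)
        rng = np.random.default_rng(6)
        X = rng.random((64, 128))
        y = np.hstack([rng.random((64, 3)), np.ones((64, 3))])
        model.fit(X, y)
        out = model.predict(X[:5])
        assert out.shape == (5, 3, 2)
        assert np.all((out > 0) & (out < 1))
        assert model.n_params_ > 0

    def test_zero_epoch_training_leaves_weights_at_init(self):
        model = TransformationNetwork(channels=6, dilations=(1,), rnn_units=4, epochs=0, seed=9)
        model.fit(np.zeros((2, 260)), np.zeros((2, 128)))
        fresh = TransformationNetwork(channels=6, dilations=(1,), rnn_units=4, seed=9)._build()
        for a, b in zip(model.model_.params, fresh.params):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_identical_history(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(64, 260)) * 0.1
        y = rng.normal(size=(64, 128)) * 0.1

        def run():
            m = TransformationNetwork(
                channels=6, dilations=(1,), rnn_units=4, epochs=2, seed=3
            )
            m.fit(X, y)
            return m.history_["mse"]

        assert run() == run()
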