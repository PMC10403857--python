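"""Network output contracts, multinomial loss oracle, and training behaviour."""

import numpy as np
import pytest

from clipnet.model import (CountWindow, ModelConfig, ProfileNet, TrainConfig,
                           combined_loss, multinomial_nll)

from conftest import random_sequence


class TestMultinomialNLL:
    def test_uniform_single_count(self):
        p = np.full(4, 0.25)
        c = np.array([1, 0, 0, 0])
        assert multinomial_nll(p, c) == pytest.approx(np.log(4), rel=1e-12)

    def test_hand_value(self):
        # -[2 log 0.5 + 1 log 0.25 + 1 log 0.25] = 2 log 2 + 4 log 2
        val = multinomial_nll([0.5, 0.25, 0.25], [2, 1, 1])
        assert val == pytest.approx(6 * np.log(2), rel=1e-12)
        assert val == pytest.approx(4.1589, abs=1e-4)

    def test_zero_counts_give_zero(self):
        assert multinomial_nll(np.full(5, 0.2), np.zeros(5)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multinomial_nll([0.5, 0.5], [1, 0, 0])

    def test_against_direct_summation_on_random_pairs(self):
        """1000 random (p, c) pairs against term-by-term summation."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            L = int(rng.integers(2, 30))
            p = rng.dirichlet(np.ones(L))
            c = rng.integers(0, 20, size=L)
            expected = -sum(ci * np.log(pi) for ci, pi in zip(c, p))
            got = multinomial_nll(p, c)
            assert got == pytest.approx(expected, rel=1e-10)
            assert got >= 0


class TestCombinedLoss:
    def _window(self, L=6, paired=True, zero=False):
        rng = np.random.default_rng(5)
        sig = np.zeros(L, dtype=int) if zero else rng.integers(0, 5, size=L)
        ctl = np.zeros(L, dtype=int) if zero else rng.integers(0, 5, size=L)
        from clipnet.genomic_io import one_hot_encode
        seq = one_hot_encode(random_sequence(rng, L))
        return CountWindow(seq, sig, ctl if paired else None)

    def _pred(self, L=6, paired=True):
        rng = np.random.default_rng(6)
        from clipnet.model import ProfilePrediction
        p_t = rng.dirichlet(np.ones(L))
        p_c = rng.dirichlet(np.ones(L))
        pi = 0.6
        if paired:
            return ProfilePrediction(pi * p_t + (1 - pi) * p_c, p_t, p_c, pi)
        return ProfilePrediction(p_t)

    def test_zero_counts(self):
        lb = combined_loss(self._pred(), self._window(zero=True))
        assert (lb.l_signal, lb.l_control, lb.l_total) == (0.0, 0.0, 0.0)

    def test_single_mode_total_is_signal_loss(self):
        lb = combined_loss(self._pred(paired=False), self._window(paired=False))
        assert lb.l_total == lb.l_signal
        assert lb.l_control == 0.0

    def test_additivity_against_nll_oracle(self):
        pred, win = self._pred(), self._window()
        lb = combined_loss(pred, win)
        assert lb.l_signal == pytest.approx(
            multinomial_nll(pred.p_total, win.signal_counts))
        assert lb.l_control == pytest.approx(
            multinomial_nll(pred.p_control, win.control_counts))
        assert lb.l_total == lb.l_signal + lb.l_control

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(self._pred(), self._window(paired=False))


class TestForwardContracts:
    @pytest.mark.parametrize("length", [50, 300, 1000])
    def test_normalization_and_mixture_identity(self, tiny_model, length):
        """Probability vectors sum to 1 and obey the additive mixture, for
        random weights and inputs of several lengths."""
        rng = np.random.default_rng(length)
        pred = tiny_model.predict_profile(random_sequence(rng, length))
        for vec in (pred.p_total, pred.p_target, pred.p_control):
            assert vec.shape == (length,)
            assert np.all(vec > 0)
            assert abs(vec.sum() - 1.0) < 1e-6
        mix = pred.pi * pred.p_target + (1 - pred.pi) * pred.p_control
        assert np.max(np.abs(pred.p_total - mix)) < 1e-6

    def test_same_weights_any_length(self, tiny_model):
        rng = np.random.default_rng(0)
        for L in (300, 500):
            assert tiny_model.predict([random_sequence(rng, L)]).shape == (1, L)

    def test_pi_endpoint_collapses_mixture(self, tiny_model):
        """Forcing the mixing logit to +inf makes p_total equal p_target."""
        rng = np.random.default_rng(1)
        x = tiny_model._encode_X([random_sequence(rng, 80)])
        bias = tiny_model.network_.pi_dense.bias
        orig = bias.data.copy()
        try:
            bias.data = bias.data + 80.0   # logistic(80) == 1.0 in float
            pred = tiny_model.predict_profiles(x)[0]
            assert pred.pi == pytest.approx(1.0)
            np.testing.assert_allclose(pred.p_total, pred.p_target, rtol=1e-12)
        finally:
            bias.data = orig

    def test_too_short_input_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="shorter"):
            tiny_model.predict(["ACGUA"])

    def test_translation_equivariance_of_peak(self, trained_model, sim_splits):
        """Prepending 20 bases shifts the predicted peak by about 20 nt on a
        strong planted-motif window (batch norm uses running statistics)."""
        te = sim_splits[2]
        i = int(np.argmax(te.pi))   # strongest-signal held-out window
        seq = te.sequences_str[i]
        peak = int(np.argmax(trained_model.predict_profile(seq).p_target))
        shifted = "ACGU" * 5 + seq
        peak2 = int(np.argmax(trained_model.predict_profile(shifted).p_target))
        assert abs(peak2 - (peak + 20)) <= 2

    def test_single_mode_has_no_pi(self, tiny_single_model):
        rng = np.random.default_rng(2)
        pred = tiny_single_model.predict_profile(random_sequence(rng, 60))
        assert pred.pi is None and pred.p_target is None
        with pytest.raises(ValueError):
            tiny_single_model.predict_pi([random_sequence(rng, 60)])


class TestConfigs:
    def test_defaults_echo(self):
        cfg = ModelConfig()
        assert (cfg.filters, cfg.first_conv_width, cfg.n_blocks,
                cfg.conv_width, cfg.dropout, cfg.head_width) == \
            (128, 12, 9, 6, 0.25, 20)
        tc = TrainConfig()
        assert (tc.learning_rate, tc.max_epochs, tc.early_stopping_patience,
                tc.lr_patience) == (0.004, 50, 10, 6)

    def test_dilation_schedule_is_exponential(self):
        cfg = ModelConfig()
        assert [cfg.dilation(i) for i in range(4)] == [2, 4, 8, 16]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(filters=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)
        with pytest.raises(ValueError):
            TrainConfig(early_stopping_patience=60)


class TestTraining:
    def _toy_data(self, n=24, L=40, seed=0):
        rng = np.random.default_rng(seed)
        X = np.stack([np.eye(4, dtype=np.float32)[rng.integers(0, 4, L)]
                      for _ in range(n)])
        y = np.stack([rng.integers(0, 3, size=(L, 2)) for _ in range(n)]
                     ).astype(np.float32)
        return X, y

    def test_early_stop_patience_arithmetic(self):
        """With a frozen network (zero LR) the validation loss never improves
        after epoch 1, so training stops at epoch 1 + patience."""
        X, y = self._toy_data()
        net = ProfileNet(filters=4, n_blocks=1, learning_rate=0.0,
                         dropout=0.0, max_epochs=50,
                         early_stopping_patience=10, batch_size=8,
                         random_state=0)
        net.fit(X, y)
        assert net.n_epochs_ == 11
        assert net.best_epoch_ == 1

    def test_smoke_training_reduces_validation_loss(self, trained_model):
        h = trained_model.history_
        assert min(h["val_loss"]) < h["val_loss"][0]
        assert trained_model.best_epoch_ >= 1

    def test_divergence_aborts_with_diagnostic(self, monkeypatch):
        """A non-finite training loss aborts with a diagnostic rather than
        silently optimising garbage (log-space losses make genuine blow-up
        hard to provoke, so a NaN weight stands in for divergence)."""
        X, y = self._toy_data()
        net = ProfileNet(filters=4, n_blocks=1, max_epochs=3,
                         early_stopping_patience=2, batch_size=8,
                         random_state=0)
        orig = ProfileNet._init_network

        def nan_init(self, rng):
            network = orig(self, rng)
            network.head_target.weight.data[:] = np.nan
            return network

        monkeypatch.setattr(ProfileNet, "_init_network", nan_init)
        with pytest.raises(RuntimeError, match="non-finite"):
            net.fit(X, y)

    def test_sklearn_param_round_trip(self):
        net = ProfileNet(filters=16, random_state=5)
        params = net.get_params()
        assert params["filters"] == 16
        clone = ProfileNet(**params)
        assert clone.get_params() == params

    def test_save_load_round_trip(self, tmp_path, trained_model, sim_splits):
        path = tmp_path / "model.npz"
        trained_model.save(path, manifest={"seed": 7})
        back = ProfileNet.load(path)
        X = sim_splits[2].sequences[:4]
        np.testing.assert_allclose(back.predict(X), trained_model.predict(X),
                                   rtol=1e-6)

    def test_inference_is_deterministic(self, trained_model, sim_splits):
        X = sim_splits[2].sequences[:2]
        a = trained_model.predict(X)
        b = trained_model.predict(X)
        np.testing.assert_array_equal(a, b)
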