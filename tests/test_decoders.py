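"""Decoders: ridge OLE with temporal CV, LSTM, smoothing, intent relabeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroloop.decoders import (LSTMDecoder, OLEWeights, RNNSpec,
                                SmootherConfig, _contiguous_folds,
                                _ridge_solve, fit_ole, load_ole, predict_ole,
                                relabel_intent, save_ole, smooth_and_scale)


def make_linear_data(rng, n=200, f=12, noise=0.0):
    X = rng.normal(size=(n, f))
    W_true = rng.normal(size=(2, f))
    b_true = rng.normal(size=2)
    Y = X @ W_true.T + b_true + noise * rng.normal(size=(n, 2))
    return X, Y, W_true, b_true


class TestOLE:
    def test_noiseless_recovery(self, rng):
        """Generative weights recovered to 1e-6 with a tiny penalty."""
        X, Y, W_true, b_true = make_linear_data(rng)
        w = fit_ole(X, Y, lambda_grid=[1e-8])
        assert np.abs(w.W - W_true).max() < 1e-6
        assert np.abs(w.b - b_true).max() < 1e-6

    def test_orthonormal_shrinkage_identity(self, rng):
        """For orthonormal designs ridge equals OLS shrunk by 1/(1+lambda)."""
        q, _ = np.linalg.qr(rng.normal(size=(60, 5)))
        X = q[:, :5]
        Y = rng.normal(size=(60, 2))
        lam = 2.5
        W_ols, _ = _ridge_solve(X, Y, 0.0, fit_intercept=False)
        W_ridge, _ = _ridge_solve(X, Y, lam, fit_intercept=False)
        assert np.allclose(W_ridge, W_ols / (1 + lam))

    def test_zero_targets_zero_weights(self, rng):
        X = rng.normal(size=(30, 4))
        w = fit_ole(X, np.zeros((30, 2)), lambda_grid=[1.0])
        assert np.allclose(w.W, 0.0, atol=1e-12)
        assert np.allclose(w.b, 0.0, atol=1e-12)

    def test_matches_sklearn_ridge(self, rng):
        """Independent cross-check of the closed-form solve."""
        from sklearn.linear_model import Ridge
        X, Y, *_ = make_linear_data(rng, noise=0.3)
        lam = 7.0
        w = fit_ole(X, Y, lambda_grid=[lam])
        sk = Ridge(alpha=lam).fit(X, Y)
        assert np.allclose(w.W, sk.coef_, atol=1e-8)
        assert np.allclose(w.b, sk.intercept_, atol=1e-8)

    def test_rank_deficient_lambda_zero_skipped(self, rng):
        X = np.tile(rng.normal(size=(30, 1)), (1, 3))  # rank 1
        Y = rng.normal(size=(30, 2))
        with pytest.warns(UserWarning, match="rank-deficient"):
            w = fit_ole(X, Y, lambda_grid=[0.0, 1.0])
        assert w.lambda_selected == 1.0

    def test_cv_folds_are_contiguous_thirds(self):
        folds = _contiguous_folds(10, 3)
        assert [f.tolist() for f in folds] == [[0, 1, 2], [3, 4, 5, 6],
                                               [7, 8, 9]]
        assert np.concatenate(folds).tolist() == list(range(10))

    def test_training_error_monotone_in_lambda(self, rng):
        """Ridge shrinks the fit: training MSE is non-decreasing in lambda."""
        X, Y, *_ = make_linear_data(rng, n=100, noise=0.5)
        errs = []
        for lam in [0.01, 0.1, 1.0, 10.0, 100.0]:
            W, b = _ridge_solve(X, Y, lam, fit_intercept=True)
            errs.append(np.mean((X @ W.T + b - Y) ** 2))
        assert all(a <= b + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_predict_matches_dot_product(self, rng):
        w = OLEWeights(W=rng.normal(size=(2, 6)), b=rng.normal(size=2),
                       lambda_selected=1.0)
        z = rng.normal(size=6)
        assert np.allclose(predict_ole(w, z), w.W @ z + w.b)

    def test_predict_dimension_mismatch(self, rng):
        w = OLEWeights(W=np.zeros((2, 6)), b=np.zeros(2), lambda_selected=1.0)
        with pytest.raises(ValueError):
            predict_ole(w, np.zeros(5))

    def test_save_load_round_trip(self, rng, tmp_path):
        X, Y, *_ = make_linear_data(rng, noise=0.1)
        w = fit_ole(X, Y)
        save_ole(w, tmp_path / "ole.json")
        back = load_ole(tmp_path / "ole.json")
        assert np.allclose(back.W, w.W)
        assert np.allclose(back.b, w.b)
        assert back.lambda_selected == w.lambda_selected


class TestLSTM:
    def test_gradients_match_finite_differences(self, rng):
        spec = RNNSpec(input_dim=3, hidden_units=4, seed=0, l2=0.01)
        dec = LSTMDecoder(spec)
        X = rng.normal(size=(2, 5, 3))
        Y = rng.normal(size=(2, 5, 2))
        loss, grads = dec._forward_backward(X, Y, None)
        eps = 1e-6
        for name in dec.params:
            flat = dec.params[name].ravel()
            for idx in range(0, flat.size, max(1, flat.size // 4)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = dec._forward_backward(X, Y, None)
                flat[idx] = orig - eps
                lm, _ = dec._forward_backward(X, Y, None)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[idx]
                assert abs(num - ana) < 1e-5 * max(1.0, abs(num))

    def test_overfits_small_dataset(self, rng):
        """Without regularization the net drives training MSE below 1%."""
        spec = RNNSpec(input_dim=4, hidden_units=16, seed=2,
                       learning_rate=1e-2, max_epochs=300,
                       plateau_patience=300)
        X = rng.normal(size=(4, 25, 4))
        Y = 0.5 * rng.normal(size=(4, 25, 2))
        dec = LSTMDecoder(spec).fit(X, Y)
        assert dec.train_losses[-1] < 0.01 * dec.train_losses[0]

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(2, 10, 3))
        Y = rng.normal(size=(2, 10, 2))
        losses = []
        for _ in range(2):
            spec = RNNSpec(input_dim=3, hidden_units=8, seed=7, max_epochs=10)
            losses.append(LSTMDecoder(spec).fit(X, Y).train_losses)
        assert losses[0] == losses[1]

    def test_output_dim_is_velocity(self, rng):
        dec = LSTMDecoder(RNNSpec(input_dim=5, hidden_units=6, seed=0))
        assert dec.step(rng.normal(size=5)).shape == (2,)

    def test_state_evolves_between_steps(self, rng):
        dec = LSTMDecoder(RNNSpec(input_dim=3, hidden_units=8, seed=1))
        dec.reset_state()
        x = rng.normal(size=3)
        assert not np.allclose(dec.step(x), dec.step(x))

    def test_stepwise_equals_batch(self, rng):
        dec = LSTMDecoder(RNNSpec(input_dim=4, hidden_units=6, seed=3))
        seq = rng.normal(size=(20, 4))
        dec.reset_state()
        stepwise = np.array([dec.step(x) for x in seq])
        assert np.array_equal(stepwise, dec.predict_sequence(seq))

    def test_zero_readout_gives_zero_output(self, rng):
        dec = LSTMDecoder(RNNSpec(input_dim=3, hidden_units=4, seed=0))
        dec.params["Wo"][:] = 0.0
        dec.params["bo"][:] = 0.0
        dec.reset_state()
        assert np.allclose(dec.step(rng.normal(size=3)), 0.0)

    def test_wrong_input_dim_rejected(self):
        dec = LSTMDecoder(RNNSpec(input_dim=3, hidden_units=4, seed=0))
        with pytest.raises(ValueError):
            dec.step(np.zeros(5))

    def test_dropout_training_still_converges(self, rng):
        spec = RNNSpec(input_dim=3, hidden_units=12, seed=1, dropout=0.2,
                       learning_rate=1e-2, max_epochs=60, plateau_patience=60)
        X = rng.normal(size=(3, 15, 3))
        Y = 0.3 * rng.normal(size=(3, 15, 2))
        dec = LSTMDecoder(spec).fit(X, Y)
        assert dec.train_losses[-1] < dec.train_losses[0]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            RNNSpec(output_dim=3)
        with pytest.raises(ValueError):
            RNNSpec(hidden_units=0)


class TestSmoother:
    def test_alpha_one_is_memoryless(self):
        cfg = SmootherConfig(alpha=1.0, gain=2.0)
        assert np.allclose(smooth_and_scale([3.0, -1.0], cfg), [6.0, -2.0])

    def test_geometric_convergence_closed_form(self):
        """Residual after k steps of constant input is (1-alpha)^k."""
        alpha = 0.3
        cfg = SmootherConfig(alpha=alpha, gain=1.0)
        v = np.array([2.0, -1.0])
        for k in range(1, 20):
            out = smooth_and_scale(v, cfg)
            expected = v * (1 - (1 - alpha) ** k)
            assert np.allclose(out, expected)

    def test_zero_gain_always_zero(self, rng):
        cfg = SmootherConfig(alpha=0.5, gain=0.0)
        for _ in range(5):
            assert np.allclose(smooth_and_scale(rng.normal(size=2), cfg), 0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.05, 1.0), st.floats(-5.0, 5.0),
           st.integers(0, 2 ** 31 - 1))
    def test_linearity_in_input(self, alpha, scale, seed):
        """Smoothing commutes with scalar multiplication of the input."""
        rng = np.random.default_rng(seed)
        seq = rng.normal(size=(10, 2))
        a, b = SmootherConfig(alpha=alpha), SmootherConfig(alpha=alpha)
        out_scaled = [smooth_and_scale(scale * v, a) for v in seq]
        out_plain = [smooth_and_scale(v, b) for v in seq]
        assert np.allclose(out_scaled, np.array(out_plain) * scale,
                           atol=1e-9)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SmootherConfig(alpha=1.5)


class TestIntentRelabeling:
    def test_on_target_zeroed(self):
        v = relabel_intent([0.1, 0.1], [0.4, 0.0], [5.0, 5.0], on_target=True)
        assert np.allclose(v, 0.0)

    def test_three_four_five_triangle(self):
        v = relabel_intent([0.0, 0.0], [3.0, 4.0], [10.0, 0.0],
                           on_target=False)
        assert np.allclose(v, [6.0, 8.0])

    def test_magnitude_preserved(self, rng):
        for _ in range(20):
            cursor, target = rng.normal(size=2), rng.normal(size=2)
            decoded = rng.normal(size=2)
            v = relabel_intent(cursor, target, decoded, on_target=False)
            assert np.linalg.norm(v) == pytest.approx(
                np.linalg.norm(decoded))

    def test_degenerate_cursor_on_target_position(self):
        v = relabel_intent([0.2, 0.2], [0.2, 0.2], [1.0, 1.0],
                           on_target=False)
        assert np.allclose(v, 0.0)
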