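"""Recurrent cells, the stacked forward pass, BPTT gradients and training."""

import numpy as np
import pytest

from pointfall.config import TrainingConfig
from pointfall.core import ParameterError
from pointfall.recurrent import (
    RecurrentModelSpec,
    forward_stacked,
    gru_cell_step,
    init_params,
    loss_and_grads,
    lstm_cell_step,
    make_windows,
    predict,
    predict_proba,
    train,
)
from pointfall.resources import count_params

TOY = dict(input_dim=4, fc1_dim=2, hidden=3, projection=2, n_classes=3, window_length=5)


def _toy_spec(variant):
    return RecurrentModelSpec(variant=variant, **TOY)


class TestCells:
    def test_lstm_zero_weights_zero_output(self):
        H = 3
        Wx, Wh, b = np.zeros((2, 4 * H)), np.zeros((H, 4 * H)), np.zeros(4 * H)
        h, c, _ = lstm_cell_step(np.zeros((1, 2)), np.zeros((1, H)), np.zeros((1, H)), Wx, Wh, b)
        assert np.allclose(h, 0.0)  # o = 0.5 but tanh(c)=0
        assert np.allclose(c, 0.0)

    def test_lstm_gates_in_unit_interval(self, rng):
        H = 4
        Wx, Wh = rng.normal(0, 0.3, (3, 4 * H)), rng.normal(0, 0.3, (H, 4 * H))
        b = rng.normal(0, 0.3, 4 * H)
        _, _, cache = lstm_cell_step(
            rng.normal(0, 1, (6, 3)), rng.normal(0, 1, (6, H)), rng.normal(0, 1, (6, H)), Wx, Wh, b
        )
        for gate in ("i", "f", "o"):
            assert np.all((cache[gate] > 0) & (cache[gate] < 1))

    def test_lstm_forget_bias_placement(self):
        H = 1
        Wx, Wh, b = np.zeros((1, 4)), np.zeros((1, 4)), np.zeros(4)
        x, h0 = np.zeros((1, 1)), np.zeros((1, 1))
        c0 = np.ones((1, 1))
        _, c_forget, _ = lstm_cell_step(x, h0, c0, Wx, Wh, b, forget_bias=1.0)
        # forget gate sigmoid(0 + 1) vs printed-form variant sigmoid(0)
        assert c_forget[0, 0] == pytest.approx(1 / (1 + np.exp(-1.0)))
        h_out, _, _ = lstm_cell_step(
            x, h0, c0, Wx, Wh, b, forget_bias=1.0, forget_bias_gate="output"
        )
        assert h_out[0, 0] == pytest.approx(1 / (1 + np.exp(-1.0)) * np.tanh(0.5))

    def test_non_finite_input_rejected(self):
        H = 2
        Wx, Wh, b = np.zeros((2, 4 * H)), np.zeros((H, 4 * H)), np.zeros(4 * H)
        with pytest.raises(ParameterError):
            lstm_cell_step(np.full((1, 2), np.nan), np.zeros((1, H)), np.zeros((1, H)), Wx, Wh, b)

    def test_gru_zero_weights_halves_state(self):
        H = 3
        Wx, Wh, b = np.zeros((2, 3 * H)), np.zeros((H, 3 * H)), np.zeros(3 * H)
        h_prev = np.array([[1.0, -2.0, 0.5]])
        h, _ = gru_cell_step(np.zeros((1, 2)), h_prev, Wx, Wh, b)
        assert np.allclose(h, h_prev / 2)  # z = 1/2, candidate = 0

    def test_gru_state_bounded_by_convexity(self, rng):
        H = 4
        Wx, Wh = rng.normal(0, 2, (3, 3 * H)), rng.normal(0, 2, (H, 3 * H))
        b = rng.normal(0, 1, 3 * H)
        h = rng.uniform(-1, 1, (5, H))
        for _ in range(20):
            h, _ = gru_cell_step(rng.normal(0, 2, (5, 3)), h, Wx, Wh, b)
        assert np.all(np.abs(h) <= 1.0 + 1e-12)


class TestParameterCounts:
    def test_fewer_gates_fewer_params(self):
        for spec_kwargs in (TOY, dict(input_dim=7, fc1_dim=32, hidden=100, projection=32,
                                      n_classes=3, window_length=20)):
            n = {v: count_params(RecurrentModelSpec(variant=v, **spec_kwargs))
                 for v in ("lstm", "bilstm", "projected_lstm", "gru")}
            assert n["gru"] < n["lstm"] < n["bilstm"]
            assert n["projected_lstm"] < n["lstm"]

    def test_count_matches_stored_weights(self):
        for variant in ("lstm", "bilstm", "projected_lstm", "gru"):
            spec = _toy_spec(variant)
            params = init_params(spec, seed=0)
            assert count_params(spec) == sum(v.size for v in params.values())


class TestForward:
    @pytest.mark.parametrize("variant", ["lstm", "bilstm", "projected_lstm", "gru"])
    def test_probabilities_normalized(self, variant, rng):
        spec = _toy_spec(variant)
        params = init_params(spec, seed=3, dtype=np.float64)
        probs = forward_stacked(rng.normal(0, 1, (8, 5, 4)), spec, params)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_zero_weights_uniform_probabilities(self, rng):
        spec = _toy_spec("lstm")
        params = {k: np.zeros_like(v) for k, v in init_params(spec, seed=0).items()}
        probs = forward_stacked(rng.normal(0, 1, (4, 5, 4)), spec, params)
        assert np.allclose(probs, 1.0 / 3.0, atol=1e-7)

    def test_bilstm_symmetric_on_palindrome(self, rng):
        spec = _toy_spec("bilstm")
        params = init_params(spec, seed=4, dtype=np.float64)
        half = rng.normal(0, 1, (1, 2, 4))
        window = np.concatenate([half, half[:, ::-1]], axis=1)
        probs_fwd = forward_stacked(window, spec, params)
        probs_rev = forward_stacked(window[:, ::-1], spec, params)
        assert np.allclose(probs_fwd, probs_rev, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        spec = _toy_spec("lstm")
        params = init_params(spec, seed=0)
        with pytest.raises(ParameterError):
            forward_stacked(rng.normal(0, 1, (2, 5, 9)), spec, params)


@pytest.mark.parametrize("variant", ["lstm", "bilstm", "projected_lstm", "gru"])
def test_gradients_match_finite_differences(variant, rng):
    """Analytic BPTT vs central differences, 1e-5 relative at toy dims."""
    spec = _toy_spec(variant)
    params = init_params(spec, seed=1, dtype=np.float64)
    X = rng.standard_normal((4, 5, 4))
    y = rng.integers(0, 3, 4)
    _, grads = loss_and_grads(X, y, spec, params)
    eps = 1e-5
    for k, v in params.items():
        flat = v.ravel()
        picks = rng.choice(flat.size, size=min(8, flat.size), replace=False)
        for idx in picks:
            old = flat[idx]
            flat[idx] = old + eps
            lp, _ = loss_and_grads(X, y, spec, params)
            flat[idx] = old - eps
            lm, _ = loss_and_grads(X, y, spec, params)
            flat[idx] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[k].ravel()[idx]
            assert abs(ana - num) / max(1e-4, abs(ana) + abs(num)) < 1e-5


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    n = 300
    X = rng.normal(0, 1, (n, 5, 4))
    y = np.where(X[:, :, 0].mean(axis=1) > 0, 1, 3)
    return X, y


class TestTraining:
    def test_loss_decreases_on_separable_data(self, toy_data):
        X, y = toy_data
        model = train(X, y, _toy_spec("lstm"), TrainingConfig(epochs=5, seed=1, batch_size=32))
        assert model.curve[-1]["train_loss"] < model.curve[0]["train_loss"]

    def test_iterations_per_epoch_floor_division(self):
        # the schedule drops the trailing partial batch: floor(6650 / 128) = 51
        assert int(13300 * 0.5) // 128 == 51

    def test_fixed_seed_reproduces_curve(self, toy_data):
        X, y = toy_data
        cfg = TrainingConfig(epochs=2, seed=9, batch_size=64)
        a = train(X, y, _toy_spec("gru"), cfg)
        b = train(X, y, _toy_spec("gru"), cfg)
        assert a.curve == b.curve  # bitwise-identical learning curve

    def test_predict_batch_equals_single(self, toy_data):
        X, y = toy_data
        model = train(X, y, _toy_spec("lstm"), TrainingConfig(epochs=1, seed=2, batch_size=64))
        batch = predict(model, X[:10])
        single = [predict(model, X[i : i + 1])[0] for i in range(10)]
        assert np.array_equal(batch, single)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ParameterError):
            train(np.empty((0, 5, 4)), np.empty(0), _toy_spec("lstm"), TrainingConfig())

    def test_save_load_round_trip(self, toy_data, tmp_path):
        X, y = toy_data
        model = train(X, y, _toy_spec("lstm"), TrainingConfig(epochs=1, seed=3, batch_size=64))
        from pointfall.recurrent import TrainedModel

        p = tmp_path / "model.npz"
        model.save(p)
        loaded = TrainedModel.load(p)
        assert np.array_equal(predict(loaded, X[:20]), predict(model, X[:20]))
        assert loaded.curve == model.curve


def test_argmax_prediction_tie_to_smallest_code():
    # probabilities (0.2, 0.5, 0.3) -> second class code
    probs = np.array([[0.2, 0.5, 0.3]])
    classes = np.array([1, 2, 3])
    assert classes[np.argmax(probs, axis=1)][0] == 2


def test_make_windows_majority_label():
    F = np.arange(24, dtype=float).reshape(12, 2)
    y = np.array([1] * 6 + [3] * 6)
    X, labels = make_windows(F, y, window_length=4, stride=4)
    assert X.shape == (3, 4, 2)
    assert list(labels) == [1, 1, 3]
    # majority in a mixed window
    _, mixed = make_windows(F, np.array([1, 1, 3, 3, 3, 1] * 2), window_length=6, stride=6)
    assert list(mixed) == [1, 1]  # 3-3 tie resolves to the smallest code
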