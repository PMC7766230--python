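import math

import numpy as np
import pytest

from airseq import (
    LSTMParams,
    LSTMState,
    SyntheticConfig,
    TrainConfig,
    WindowSpec,
    build_variant,
    generate_station,
    lstm_cell_step,
    predict,
    train,
)
from airseq.errors import AirseqError, NotFittedError
from airseq.models import Seq2SeqForecaster, evaluate_loss, load_model, save_model
from airseq.nn import zero_state
from airseq.windowing import SampleWindow

from oracles import lstm_step_bruteforce


# ----------------------------------------------------------------------
# cell-level contracts
# ----------------------------------------------------------------------
def test_zero_parameter_cell_is_identity_to_zero():
    params = LSTMParams.zeros(3, 4)
    state = zero_state(4)
    out = lstm_cell_step(params, np.zeros(3), state)
    assert np.allclose(out.h, 0.0) and np.allclose(out.c, 0.0)


def test_scalar_all_ones_cell():
    """Hand-checkable scalar case: c = sigmoid(1)*tanh(1), h = sigmoid(1)*tanh(c)."""
    params = LSTMParams(W=np.ones((4, 1)), U=np.ones((4, 1)), b=np.zeros(4))
    out = lstm_cell_step(params, np.array([1.0]), zero_state(1))
    sig1 = 1.0 / (1.0 + math.exp(-1.0))
    c_expect = sig1 * math.tanh(1.0)
    h_expect = sig1 * math.tanh(c_expect)
    assert out.c[0] == pytest.approx(c_expect, abs=1e-12)
    assert out.h[0] == pytest.approx(h_expect, abs=1e-12)


def test_cell_matches_scalar_bruteforce_oracle():
    """100 random small cells agree with the literal per-component loops."""
    rng = np.random.default_rng(17)
    worst = 0.0
    for _ in range(100):
        D = int(rng.integers(1, 5))
        H = int(rng.integers(1, 6))
        params = LSTMParams(
            W=rng.normal(size=(4 * H, D)),
            U=rng.normal(size=(4 * H, H)),
            b=rng.normal(size=4 * H),
        )
        x = rng.normal(size=D)
        h_prev = rng.normal(size=H) * 0.5
        c_prev = rng.normal(size=H)
        out = lstm_cell_step(params, x, LSTMState(h_prev.copy(), c_prev.copy()))
        h_ref, c_ref, gates = lstm_step_bruteforce(
            params.W_i, params.W_f, params.W_o, params.W_c,
            params.U_i, params.U_f, params.U_o, params.U_c,
            params.b_i, params.b_f, params.b_o, params.b_c,
            x, h_prev, c_prev,
        )
        worst = max(worst, float(np.max(np.abs(out.h - h_ref))),
                    float(np.max(np.abs(out.c - c_ref))))
        for i, f, o, g in gates:
            assert 0.0 < i < 1.0 and 0.0 < f < 1.0 and 0.0 < o < 1.0
            assert abs(g) < 1.0
        assert np.all(np.abs(out.h) < 1.0)
    assert worst < 1e-10


def test_cell_shape_errors():
    params = LSTMParams.zeros(3, 4)
    with pytest.raises(AirseqError):
        lstm_cell_step(params, np.zeros(5), zero_state(4))
    with pytest.raises(AirseqError):
        lstm_cell_step(params, np.zeros(3), zero_state(2))


# ----------------------------------------------------------------------
# encoder / decoder contracts
# ----------------------------------------------------------------------
def _tiny_spec(**kw):
    return WindowSpec(target_pollutant="pm25", feature_set="target_only", **kw)


def test_encode_zero_params_and_dimension():
    model = build_variant("seq2seq_weekly", _tiny_spec(), hidden_size=6, seed=0)
    model.enc.W[...] = 0.0
    model.enc.U[...] = 0.0
    model.enc.b[...] = 0.0
    x = np.random.default_rng(0).normal(size=(24, model.window_spec.n_features))
    h, c = model.encode(x)
    assert h.shape == (6,) and c.shape == (6,)
    assert np.allclose(h, 0.0) and np.allclose(c, 0.0)


def test_encode_order_sensitivity():
    """Swapping two input rows changes the context (recurrence is ordered)."""
    model = build_variant("seq2seq_weekly", _tiny_spec(), hidden_size=8, seed=3)
    x = np.random.default_rng(4).normal(size=(24, model.window_spec.n_features))
    h1, _ = model.encode(x)
    xs = x.copy()
    xs[[2, 20]] = xs[[20, 2]]
    h2, _ = model.encode(xs)
    assert not np.allclose(h1, h2)


def test_decode_zero_params_and_length():
    model = build_variant("seq2seq", _tiny_spec(), hidden_size=5, seed=0)
    for arr in model.parameters().values():
        arr[...] = 0.0
    out = model.decode((np.zeros(5), np.zeros(5)))
    assert out.shape == (24,)
    assert np.allclose(out, 0.0)


def test_decode_depends_on_context():
    model = build_variant("seq2seq", _tiny_spec(), hidden_size=8, seed=5)
    rng = np.random.default_rng(6)
    c1 = (rng.normal(size=8) * 0.5, rng.normal(size=8))
    c2 = (rng.normal(size=8) * 0.5, rng.normal(size=8))
    y1 = model.decode(c1)
    y2 = model.decode(c2)
    assert y1.shape == (24,) and not np.allclose(y1, y2)


def test_gradients_match_finite_differences():
    """Backprop agrees with central finite differences on a tiny model."""
    rng = np.random.default_rng(0)
    for variant in ("seq2seq_weekly", "bilstm"):
        model = build_variant(variant, _tiny_spec(), hidden_size=3, seed=3)
        F = model.window_spec.n_features
        xb = rng.normal(size=(2, 24, F))
        yb = rng.normal(size=(2, 24))
        tf_mask = rng.random(24) < 0.5
        _, grads = model.loss_and_grads(xb, yb, tf_mask)
        eps = 1e-6
        for name, p in model.parameters().items():
            flat = p.ravel()
            g = grads[name].ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp, _ = model.loss_and_grads(xb, yb, tf_mask)
                flat[i] = old - eps
                lm, _ = model.loss_and_grads(xb, yb, tf_mask)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-8), name


# ----------------------------------------------------------------------
# variants
# ----------------------------------------------------------------------
def test_build_variant_widths_and_param_counts():
    spec = _tiny_spec()
    weekly = build_variant("seq2seq_weekly", spec, hidden_size=16)
    plain = build_variant("seq2seq", spec, hidden_size=16)
    assert weekly.window_spec.n_features == plain.window_spec.n_features + 1
    assert weekly.enc.input_size == plain.enc.input_size + 1

    lstm = build_variant("lstm", spec, hidden_size=16)
    bilstm = build_variant("bilstm", spec, hidden_size=16)
    assert bilstm.encoder_param_count == 2 * lstm.encoder_param_count

    with pytest.raises(ValueError, match="unknown variant"):
        build_variant("gru", spec)


def test_mean_context_rule():
    model = build_variant("seq2seq_weekly", _tiny_spec(), hidden_size=4,
                          context_rule="mean", seed=1)
    x = np.random.default_rng(2).normal(size=(24, model.window_spec.n_features))
    h_mean, _ = model.encode(x)
    model.context_rule = "final"
    h_final, _ = model.encode(x)
    assert not np.allclose(h_mean, h_final)


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------
def _constant_samples(n, F, rng, level=0.5):
    return [
        SampleWindow(x=rng.normal(0.5, 0.1, size=(24, F)),
                     y=np.full(24, level), target_date=None)
        for _ in range(n)
    ]


def test_train_constant_targets_converges():
    """Degenerate constant-target data is fit to RMSE < 0.05 within 50 epochs."""
    rng = np.random.default_rng(11)
    spec = _tiny_spec()
    model = build_variant("seq2seq_weekly", spec, hidden_size=8, seed=1)
    samples = _constant_samples(32, model.window_spec.n_features, rng)
    cfg = TrainConfig(epochs=50, batch_size=16, patience=50, seed=0)
    history = train(model, samples, cfg)
    assert len(history) <= 50
    final = math.sqrt(evaluate_loss(model, samples))
    assert final < 0.05
    assert history[-1]["train_loss"] < history[0]["train_loss"]


def test_train_deterministic_history():
    rng = np.random.default_rng(12)
    spec = _tiny_spec()
    F = build_variant("seq2seq_weekly", spec, hidden_size=6).window_spec.n_features
    samples = _constant_samples(16, F, rng)
    histories = []
    for _ in range(2):
        model = build_variant("seq2seq_weekly", spec, hidden_size=6, seed=4)
        histories.append(train(model, samples, TrainConfig(epochs=8, seed=9)))
    assert histories[0] == histories[1]


def test_train_input_validation():
    spec = _tiny_spec()
    model = build_variant("lstm", spec, hidden_size=4)
    with pytest.raises(ValueError):
        train(model, [], TrainConfig(epochs=1))
    with pytest.raises(ValueError):
        TrainConfig(teacher_forcing_ratio=1.5)


# ----------------------------------------------------------------------
# prediction and persistence
# ----------------------------------------------------------------------
def test_predict_inverse_scaling_and_guards(tmp_path):
    from airseq import Scaler, build_samples

    s = generate_station(SyntheticConfig(n_days=20, missing_rate=0.0, seed=3))
    scaler = Scaler().fit(s.data)
    spec = WindowSpec(target_pollutant="co", feature_set="target_only")
    samples = build_samples(s, spec, scaler)
    model = build_variant("seq2seq_weekly", spec, hidden_size=6, seed=2)

    with pytest.raises(NotFittedError):
        predict(model, samples[0], scaler)

    train(model, samples[:10], TrainConfig(epochs=2, seed=0))
    out = predict(model, samples[0], scaler)
    assert out.shape == (24,) and np.isfinite(out).all()
    # composition contract: prediction = inverse(scaled forward pass)
    scaled = model.forward(samples[0].x[None])[0]
    assert np.allclose(out, scaler.inverse_values(scaled, "co"))

    from airseq import Scaler as S

    with pytest.raises(NotFittedError):
        predict(model, samples[0], S())

    # JSON checkpoint round trip
    path = tmp_path / "model.json"
    save_model(model, path, scaler=scaler)
    loaded, loaded_scaler = load_model(path)
    assert np.allclose(loaded.forward(samples[0].x[None]), model.forward(samples[0].x[None]))
    assert loaded_scaler.scale_ == scaler.scale_


def test_model_beats_mean_predictor_on_periodic_data():
    """On noise-free periodic data the trained model beats the mean forecast."""
    from airseq import Scaler, build_samples, split_series

    cfg = SyntheticConfig(n_days=60, noise_sd=0.0, meteo_coupling={},
                          missing_rate=0.0, seed=5)
    s = generate_station(cfg)
    train_s, val_s, test_s = split_series(s)
    scaler = Scaler().fit(train_s.data)
    spec = WindowSpec(target_pollutant="pm25", feature_set="target_only")
    model = build_variant("seq2seq_weekly", spec, hidden_size=16, seed=0)
    tr = build_samples(train_s, model.window_spec, scaler)
    te = build_samples(test_s, model.window_spec, scaler)
    train(model, tr, TrainConfig(epochs=40, patience=40, seed=0))
    obs = np.concatenate([scaler.inverse_values(w.y, "pm25") for w in te])
    pred = np.concatenate([predict(model, w, scaler) for w in te])
    rmse_model = float(np.sqrt(np.mean((obs - pred) ** 2)))
    assert rmse_model < float(s.channel("pm25").std())
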