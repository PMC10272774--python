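"""Bi-LSTM regressor: gradients, architecture audit, learnability,
determinism and persistence."""

import numpy as np
import pytest

from synergykit import _lstm
from synergykit.decompose import SynergyDecomposition
from synergykit.errors import ArgumentError
from synergykit.kinematics import AngleTrace
from synergykit.regress import (
    BiLSTMRegressor,
    RegressorConfig,
    build_features,
    predict,
    train,
)
from synergykit.synthetic import make_activation_profiles, make_ground_truth


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

def test_backprop_matches_finite_differences():
    """Analytic BPTT gradients agree with central differences on a small
    float64 network (2 Bi-LSTM layers, 3 units)."""
    rng = np.random.default_rng(0)
    params, out = _lstm.init_bilstm_params(2, 3, 2, rng, dtype=np.float64)
    x = rng.standard_normal((2, 5, 2))
    y = rng.standard_normal((2, 5))

    def loss_fn():
        yp, _, _ = _lstm.bilstm_forward(x, params, out, train=False)
        return _lstm.mse_loss_and_grad(yp, y)[0]

    yp, hidden, caches = _lstm.bilstm_forward(x, params, out, train=False)
    _, dy = _lstm.mse_loss_and_grad(yp, y)
    grads, grads_out = _lstm.bilstm_backward(dy, hidden, caches, params, out)
    flat_p = _lstm.flatten_params(params, out)
    flat_g = _lstm.flatten_params(grads, grads_out)
    eps = 1e-6
    for p, g in zip(flat_p, flat_g):
        for _ in range(min(p.size, 4)):
            idx = tuple(rng.integers(0, s) for s in p.shape) if p.ndim else ()
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss_fn()
            p[idx] = orig - eps
            lm = loss_fn()
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - g[idx]) <= 1e-4 * max(abs(num), abs(g[idx]), 1e-3)


def test_parameter_count_matches_architecture():
    """Five bidirectional layers x 48 hidden units + per-step readout."""
    model = BiLSTMRegressor()
    assert (model.n_layers, model.hidden_units, model.dropout) == (5, 48, 0.3)
    rng = np.random.default_rng(0)
    params, out = _lstm.init_bilstm_params(2, 48, 5, rng)
    H = 48

    def gates(fan_in):
        return (fan_in + H + 1) * 4 * H

    expected = 2 * gates(2) + 2 * 4 * gates(2 * H) + (2 * H + 1)
    assert _lstm.count_params(params, out) == expected


# ---------------------------------------------------------------------------
# estimator behaviour
# ---------------------------------------------------------------------------

def _fit_small(**kw):
    rng = np.random.default_rng(1)
    n = 400
    X = rng.random((n, 2))
    y = np.full(n, 37.0)
    defaults = dict(window_length=100, stride=50, epochs=5, random_state=0)
    defaults.update(kw)
    return BiLSTMRegressor(**defaults).fit(X, y), X, y


def test_constant_target_learned_within_one_degree():
    model, X, y = _fit_small()
    pred = model.predict(X)
    assert np.max(np.abs(pred - 37.0)) < 1.0


def test_prediction_length_and_determinism():
    model, X, _ = _fit_small()
    p1, p2 = model.predict(X), model.predict(X)
    assert p1.shape == (X.shape[0],)
    assert np.array_equal(p1, p2)


def test_training_reproducible_with_seed():
    m1, X, y = _fit_small(random_state=3)
    m2, _, _ = _fit_small(random_state=3)
    assert np.array_equal(m1.training_log_, m2.training_log_)
    assert np.array_equal(m1.predict(X), m2.predict(X))


def test_too_short_sequence_rejected():
    with pytest.raises(ArgumentError):
        BiLSTMRegressor(window_length=100).fit(np.zeros((50, 2)), np.zeros(50))


def test_feature_dim_mismatch_at_predict_rejected():
    model, _, _ = _fit_small()
    with pytest.raises(ArgumentError):
        model.predict(np.zeros((100, 3)))


def test_save_load_round_trip_bit_exact(tmp_path):
    model, X, _ = _fit_small()
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = BiLSTMRegressor.load(path)
    assert np.array_equal(model.predict(X), loaded.predict(X))
    for a, b in zip(
        _lstm.flatten_params(model.params_, model.out_),
        _lstm.flatten_params(loaded.params_, loaded.out_),
    ):
        assert np.array_equal(a, b)


def test_internal_standardization_uses_training_stats():
    model, X, _ = _fit_small()
    Z = (X - model.x_mean_) / model.x_std_
    assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(Z.std(axis=0), 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _decomp(C, S):
    return SynergyDecomposition(
        C=C, S=S, method="mcr_als", r=C.shape[1], n_iter=1,
        objective_trace=np.zeros(1), vaf=1.0,
    )


def test_build_features_shape_and_matching():
    rng = np.random.default_rng(2)
    C = np.abs(rng.standard_normal((3, 2)))
    S = np.abs(rng.standard_normal((2, 50)))
    ref = _decomp(C, S)
    swapped = _decomp(C[:, ::-1], S[::-1])
    F_ref = build_features(ref, reference=ref)
    F_swapped = build_features(swapped, reference=ref)
    assert F_ref.shape == (2, 50)
    assert np.allclose(F_ref, F_swapped)


def test_build_features_invariant_to_factor_scale_split():
    rng = np.random.default_rng(3)
    C = np.abs(rng.standard_normal((3, 2)))
    S = np.abs(rng.standard_normal((2, 50)))
    a = build_features(_decomp(C, S))
    b = build_features(_decomp(C / 4.0, 4.0 * S))
    assert np.allclose(a, b, rtol=1e-12)


# ---------------------------------------------------------------------------
# learnability of the activation -> angle map
# ---------------------------------------------------------------------------

def test_invertible_activation_angle_map_learned_on_held_out_cycles():
    """Trained on clean ground-truth activations, the network must track
    the angle on a freshly jittered activation sequence (CC >= 0.95)."""
    from synergykit import pearson_cc

    truth = make_ground_truth(n_cycles=8, seed=21, noise_sigma=0.0)
    feats = truth.S_true
    angles = AngleTrace(truth.angle_true, truth.sampling_rate)
    model = train(feats, angles, RegressorConfig(seed=0))
    held_out = make_activation_profiles(8, 200, 2, seed=99)
    pred = predict(model, held_out, truth.sampling_rate)
    cc = pearson_cc(pred.theta, truth.angle_true)
    assert cc >= 0.95
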