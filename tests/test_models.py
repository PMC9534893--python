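"""Tests of the from-scratch MLP and RBF networks and the trait surrogate."""

import numpy as np
import pytest

import gabamorph as gm
from gabamorph.exceptions import ParameterError
from gabamorph.models import (
    MLPConfig,
    MLPNetwork,
    rbf_design_matrix,
    train_mlp,
    train_rbf,
)
from gabamorph.preprocessing import FeatureEncoding, encode_records
from gabamorph.surrogate import fit_surrogate


# ---------------------------------------------------------------------------
# MLP forward pass
# ---------------------------------------------------------------------------

def test_zero_weights_output_equals_bias():
    net = MLPNetwork(
        [np.zeros((3, 4)), np.zeros((4, 2))],
        [np.zeros(4), np.array([0.7, -1.2])],
    )
    pred = net.forward(np.random.default_rng(0).normal(size=(6, 3)))
    assert np.allclose(pred, [0.7, -1.2])


def test_toy_111_net_at_zero_input():
    net = MLPNetwork([np.ones((1, 1)), np.ones((1, 1))], [np.zeros(1), np.zeros(1)])
    assert net.forward(np.array([[0.0]]))[0, 0] == pytest.approx(0.0)


def test_toy_221_net_hand_evaluation():
    # tanh(1) + tanh(-1) + 0.5 = 0.5
    net = MLPNetwork(
        [np.eye(2), np.array([[1.0], [1.0]])],
        [np.zeros(2), np.array([0.5])],
    )
    assert net.forward(np.array([[1.0, -1.0]]))[0, 0] == pytest.approx(0.5, abs=1e-12)


def test_forward_shape_mismatch_raises():
    net = MLPNetwork([np.zeros((3, 2)), np.zeros((2, 1))], [np.zeros(2), np.zeros(1)])
    with pytest.raises(ParameterError):
        net.forward(np.zeros((4, 5)))


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(2)
    net = MLPNetwork.initialize((3, 5, 4, 2), seed=2)
    X = rng.normal(size=(12, 3))
    Y = rng.normal(size=(12, 2))
    p0 = net.get_params()
    _, grad = net.loss_grad(X, Y, l2=1e-3)
    eps = 1e-6
    for idx in rng.choice(p0.size, size=12, replace=False):
        for sign, store in ((1, "hi"), (-1, "lo")):
            p = p0.copy()
            p[idx] += sign * eps
            net.set_params(p)
            val = net.loss_grad(X, Y, l2=1e-3)[0]
            if sign == 1:
                hi = val
            else:
                lo = val
        assert grad[idx] == pytest.approx((hi - lo) / (2 * eps), rel=1e-4, abs=1e-8)
    net.set_params(p0)


# ---------------------------------------------------------------------------
# MLP training
# ---------------------------------------------------------------------------

def test_fits_noise_free_linear_target():
    x = np.linspace(-1, 1, 50)[:, None]
    y = 2.0 * x
    net = train_mlp(x, y, MLPConfig(hidden_layers=(8,), l2=0.0, max_iter=800, seed=0))
    mse = float(np.mean((net.forward(x) - y) ** 2))
    assert mse < 1e-3


def test_constant_target_absorbed_by_bias():
    x = np.linspace(-1, 1, 20)[:, None]
    y = np.full((20, 1), 0.37)
    net = train_mlp(x, y, MLPConfig(hidden_layers=(4,), l2=0.0, max_iter=400, seed=1))
    assert float(np.mean((net.forward(x) - y) ** 2)) < 1e-8


def test_objective_history_non_increasing():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 4))
    Y = np.sin(X[:, :1]) + 0.1 * X[:, 1:2]
    net = train_mlp(X, Y, MLPConfig(max_iter=300, seed=3))
    hist = np.asarray(net.history)
    assert np.all(np.diff(hist) <= 1e-12)
    assert hist[-1] <= hist[0]


def test_training_is_seed_deterministic():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(40, 3))
    Y = rng.normal(size=(40, 2))
    a = train_mlp(X, Y, MLPConfig(max_iter=150, seed=9))
    b = train_mlp(X, Y, MLPConfig(max_iter=150, seed=9))
    assert all(np.array_equal(w1, w2) for w1, w2 in zip(a.weights, b.weights))
    assert all(np.array_equal(b1, b2) for b1, b2 in zip(a.biases, b.biases))


def test_evidence_reestimation_updates_penalty():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(40, 2))
    Y = X[:, :1] * 0.5 + 0.05 * rng.normal(size=(40, 1))
    net = train_mlp(
        X, Y,
        MLPConfig(hidden_layers=(5,), l2=1e-3, max_iter=200, seed=5,
                  reestimate_l2=True, n_reestimate=2),
    )
    assert net.final_l2 != 1e-3  # the evidence update moved the penalty
    assert float(np.mean((net.forward(X) - Y) ** 2)) < 0.05


# ---------------------------------------------------------------------------
# RBF
# ---------------------------------------------------------------------------

def test_rbf_feature_values():
    c = np.array([[1.0, 2.0]])
    widths = np.array([0.5])
    assert rbf_design_matrix(np.array([[1.0, 2.0]]), c, widths)[0, 0] == pytest.approx(1.0)
    x = np.array([[1.0 + 0.5, 2.0 + 0.5]])  # distance sigma*sqrt(2)
    assert rbf_design_matrix(x, c, widths)[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)
    far = rbf_design_matrix(np.array([[50.0, 50.0]]), c, widths)[0, 0]
    assert 0.0 <= far < 1e-10


def test_rbf_interpolation_limit():
    rng = np.random.default_rng(6)
    X = rng.uniform(-1, 1, size=(30, 2))
    Y = np.sin(3 * X[:, :1]) * np.cos(2 * X[:, 1:2])
    net = train_rbf(X, Y, k=30, centers=X, widths=0.05, ridge=0.0)
    assert np.abs(net.forward(X) - Y).max() < 1e-6


def test_rbf_single_center_closed_form():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(25, 1))
    y = rng.normal(size=(25, 1))
    center = np.array([[0.3]])
    net = train_rbf(X, y, centers=center, widths=1.2, ridge=0.0)
    phi = rbf_design_matrix(X, center, np.array([1.2]))
    expected = float(phi.ravel() @ y.ravel() / (phi.ravel() @ phi.ravel()))
    assert net.weights[0, 0] == pytest.approx(expected, rel=1e-10)


def test_rbf_k_exceeding_rows_rejected():
    with pytest.raises(ParameterError):
        train_rbf(np.zeros((5, 2)), np.zeros((5, 1)), k=6)


def test_rbf_overfits_in_interpolation_regime():
    """K = N with narrow widths drives train error to ~0 but test error
    above train error on noisy data (the overfitting direction).  A
    single-replicate design keeps the training inputs distinct so the
    interpolation system stays well-posed."""
    design = gm.pomegranate_design(replicates=1)
    params = gm.default_generator_params(3)
    frame = gm.generate_morphology(design, params)
    enc = FeatureEncoding()
    X, Y = encode_records(frame, enc)
    split = gm.split_data(len(frame), 0.8, seed=2)
    model = fit_surrogate(
        X, Y, split.train_idx, "rbf",
        rbf_params={"k": len(split.train_idx), "widths": 0.05, "ridge": 1e-12},
    )
    tr = split.train_idx
    train_rmse = float(np.sqrt(np.mean((model.predict_encoded(X[tr]) - Y[tr]) ** 2)))
    te = split.test_idx
    test_rmse = float(np.sqrt(np.mean((model.predict_encoded(X[te]) - Y[te]) ** 2)))
    assert train_rmse < 1e-4
    assert test_rmse > train_rmse


# ---------------------------------------------------------------------------
# trait surrogate
# ---------------------------------------------------------------------------

def _interpolating_surrogate():
    design = gm.pomegranate_design(replicates=1)
    params = gm.default_generator_params(0)
    params.noise_sd = {t: 0.0 for t in gm.TRAITS}
    frame = gm.generate_morphology(design, params)
    enc = FeatureEncoding()
    X, Y = encode_records(frame, enc)
    model = fit_surrogate(
        X, Y, kind="rbf", encoding=enc,
        rbf_params={"k": len(X), "widths": 0.05, "ridge": 0.0},
    )
    return frame, model


def test_predict_traits_round_trip_with_interpolating_rbf():
    frame, model = _interpolating_surrogate()
    row = frame.iloc[17]
    pred = model.predict_traits(row.cultivar, row.stress, row.gaba_mM, row.day)
    for t in gm.TRAITS:
        assert pred[t] == pytest.approx(row[t], abs=1e-4)


def test_predictions_deterministic_and_smooth(trained_mlp):
    a = trained_mlp.predict_traits("Atabaki", "control", 12.0, 30.0)
    b = trained_mlp.predict_traits("Atabaki", "control", 12.0, 30.0)
    assert a == b
    doses = np.arange(0.0, 40.0, 0.5)
    rows = np.array([[1.0, 0.0, d, 30.0] for d in doses])
    preds = trained_mlp.predict_encoded(rows)
    grad = np.abs(np.diff(preds, axis=0) / 0.5)
    assert grad.max() < 50.0  # bounded finite-difference gradient in dose


def test_surrogate_json_round_trip(tmp_path, trained_rbf):
    path = tmp_path / "model.json"
    trained_rbf.save(path)
    loaded = gm.TraitSurrogate.load(path)
    X = np.array([[1.0, 2.0, 15.0, 20.0], [2.0, 0.0, 0.0, 45.0]])
    assert np.array_equal(loaded.predict_encoded(X), trained_rbf.predict_encoded(X))
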