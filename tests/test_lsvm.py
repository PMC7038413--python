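"""LSVM trainer against generic quadratic-programming oracles."""

import numpy as np
import pytest

from afdetect import (
    LSVMConfig,
    lsvm_train,
    rbf_kernel,
    scale_apply,
    scale_fit,
)
from afdetect.lsvm import LSVMModel, ScalingParams, _augment
from oracles import qp_dual, qp_primal


def random_linear_instance(rng, n_max=100, t=5, margin_noise=0.3):
    n = int(rng.integers(10, n_max + 1))
    X = rng.normal(size=(n, t))
    w = rng.normal(size=t)
    y = np.where(X @ w + margin_noise * rng.normal(size=n) > 0, 1.0, -1.0)
    return (X, y) if len(np.unique(y)) == 2 else random_linear_instance(rng, n_max, t)


# -- scaling ---------------------------------------------------------------


def test_scaling_examples():
    params = scale_fit(np.array([[0.0], [10.0]]))
    np.testing.assert_allclose(scale_apply(params, np.array([[0.0], [10.0]])), [[-1.0], [1.0]])
    assert scale_apply(params, np.array([[5.0]]))[0, 0] == 0.0
    assert scale_apply(params, np.array([[20.0]]))[0, 0] == 3.0  # no clipping


def test_scaling_constant_feature_maps_to_zero():
    params = scale_fit(np.array([[4.0, 1.0], [4.0, 3.0]]))
    out = scale_apply(params, np.array([[4.0, 2.0], [4.0, 99.0]]))
    assert (out[:, 0] == 0.0).all()


def test_scaling_feature_count_mismatch():
    params = scale_fit(np.array([[0.0, 1.0]]))
    with pytest.raises(ValueError, match="feature count"):
        scale_apply(params, np.array([[1.0]]))


# -- kernel ----------------------------------------------------------------


def test_rbf_unit_diagonal_and_value(rng):
    x = rng.normal(size=(1, 4))
    assert rbf_kernel(x, x, 2.5)[0, 0] == 1.0
    a, b = np.zeros((1, 2)), np.array([[1.0, 0.0]])  # squared distance 1
    assert rbf_kernel(a, b, 4.0)[0, 0] == pytest.approx(np.exp(-4.0))


def test_rbf_gram_is_psd(rng):
    X = rng.normal(size=(50, 6))
    K = rbf_kernel(X, X, 0.7)
    np.testing.assert_allclose(K, K.T)
    assert np.linalg.eigvalsh(K).min() >= -1e-10


def test_rbf_rejects_nonpositive_chi():
    with pytest.raises(ValueError, match="chi"):
        rbf_kernel(np.zeros((1, 2)), np.zeros((1, 2)), 0.0)


# -- training --------------------------------------------------------------


def test_two_point_separable_boundary():
    """Symmetric +/-1 points at large gamma put the boundary at ~0."""
    X = np.array([[1.0], [-1.0]])
    y = np.array([1.0, -1.0])
    cfg = LSVMConfig(gamma=1e5, kernel="linear", max_iter=10000, tol=1e-10)
    m = lsvm_train(X, y, cfg, prescaled=True)
    assert abs(m.w0 / m.w[0]) < 1e-3
    scores = m.decision(X, scaled=True)
    assert scores[0] > 0 > scores[1]


def test_linear_matches_primal_qp_oracle(rng):
    """(w, w0) agree with a generic solve of the squared-slack primal."""
    for _ in range(5):
        X, y = random_linear_instance(rng, n_max=60)
        cfg = LSVMConfig(gamma=10.0, kernel="linear", max_iter=50000, tol=1e-10)
        m = lsvm_train(X, y, cfg, prescaled=True)
        w_qp, w0_qp = qp_primal(X, y, 10.0)
        got = np.r_[m.w, m.w0]
        want = np.r_[w_qp, w0_qp]
        assert np.linalg.norm(got - want) / np.linalg.norm(want) < 1e-4


def test_dual_matches_bound_constrained_qp(rng):
    """lambda agrees with an L-BFGS-B solve of the dual to 1e-3 relative."""
    X, y = random_linear_instance(rng, n_max=80)
    cfg = LSVMConfig(gamma=10.0, kernel="linear", max_iter=50000, tol=1e-10)
    m = lsvm_train(X, y, cfg, prescaled=True)
    H = y[:, None] * _augment(X)
    lam_qp = qp_dual(np.eye(len(y)) / 10.0 + H @ H.T)
    assert np.linalg.norm(m.lam - lam_qp) / np.linalg.norm(lam_qp) < 1e-3


def test_xor_with_gaussian_kernel():
    X = np.array([[1.0, 1.0], [-1.0, -1.0], [1.0, -1.0], [-1.0, 1.0]])
    y = np.array([1.0, 1.0, -1.0, -1.0])
    m = lsvm_train(X, y, LSVMConfig(gamma=10.0, chi=4.0, max_iter=1000, tol=1e-9),
                   prescaled=True)
    np.testing.assert_array_equal(m.predict(X, scaled=True), y)


def test_kernel_decision_equals_dual_expansion(rng):
    """Scores equal a hand-rolled loop over support terms to 1e-10."""
    X, y = random_linear_instance(rng, n_max=40)
    m = lsvm_train(X, y, LSVMConfig(gamma=10.0, chi=1.0))
    Xq = rng.normal(size=(5, X.shape[1]))
    got = m.decision(Xq)
    Xq_s = m.scaler.apply(Xq)
    for row, score in zip(Xq_s, got):
        total = 0.0
        for xi, yi, li in zip(m.X0, m.y, m.lam):
            d2 = float(np.sum((row - xi) ** 2))  # the -1 padding cancels
            total += yi * li * np.exp(-1.0 * d2)
        assert score == pytest.approx(total, abs=1e-10)


def test_prediction_tie_and_sign_mapping():
    model = LSVMModel(
        config=LSVMConfig(kernel="linear"),
        scaler=ScalingParams(np.array([-1.0]), np.array([1.0])),
        lam=np.zeros(2), y=np.array([1.0, -1.0]), X0=np.zeros((2, 1)),
        w=np.array([1.0]), w0=0.0, iterations_run=1, converged=True,
    )
    assert model.predict(np.array([[0.5]]))[0] == 1
    assert model.predict(np.array([[-0.5]]))[0] == -1
    assert model.predict(np.array([[0.0]]))[0] == -1  # exact tie -> non-AF


def test_training_order_invariance(rng):
    X, y = random_linear_instance(rng, n_max=50)
    cfg = LSVMConfig(gamma=10.0, chi=2.0, max_iter=2000, tol=1e-9)
    m1 = lsvm_train(X, y, cfg)
    perm = rng.permutation(len(y))
    m2 = lsvm_train(X[perm], y[perm], cfg)
    Xq = rng.normal(size=(20, X.shape[1]))
    np.testing.assert_allclose(m1.decision(Xq), m2.decision(Xq), atol=1e-6)


def test_residuals_eventually_decrease(rng):
    X, y = random_linear_instance(rng, n_max=80)
    m = lsvm_train(X, y, LSVMConfig(gamma=10.0, kernel="linear",
                                    max_iter=2000, tol=1e-10), prescaled=True)
    r = m.residual_history
    assert m.converged
    tail = r[len(r) // 2 :]
    assert (np.diff(tail) <= 1e-12).all()  # linear convergence in the tail
    assert r[-1] < r[0]


def test_config_validation():
    with pytest.raises(ValueError, match="convergence band"):
        LSVMConfig(gamma=10.0, alpha=0.3)  # 0.3 >= 2/10
    assert LSVMConfig(gamma=7.0).effective_alpha == pytest.approx(1.9 / 7.0)
    with pytest.raises(ValueError):
        LSVMConfig(gamma=-1.0)


def test_training_input_errors(rng):
    X = rng.normal(size=(10, 3))
    with pytest.raises(ValueError, match="each class"):
        lsvm_train(X, np.ones(10))
    Xbad = X.copy()
    Xbad[0, 0] = np.nan
    y = np.r_[np.ones(5), -np.ones(5)]
    with pytest.raises(ValueError, match="non-finite"):
        lsvm_train(Xbad, y)


def test_model_roundtrip_bit_identical(tmp_path, rng):
    X, y = random_linear_instance(rng, n_max=30)
    m = lsvm_train(X, y, LSVMConfig(gamma=10.0, chi=4.0))
    path = tmp_path / "model.json"
    m.save(path)
    m2 = LSVMModel.load(path)
    Xq = rng.normal(size=(10, X.shape[1]))
    assert np.array_equal(m.decision(Xq), m2.decision(Xq))
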