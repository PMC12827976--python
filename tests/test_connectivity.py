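"""Connectivity matrices, recognition gains, centrality and Lyapunov."""

import numpy as np
import pytest
from scipy import linalg

from emadyn.connectivity import (ConnectivityMatrix, connectivity,
                                 connectivity_kalman, connectivity_plrnn,
                                 connectivity_var, group_edge_significance,
                                 lyapunov_qr, plrnn_local_jacobian,
                                 recognition_gain_kalman,
                                 recognition_gain_plrnn,
                                 trajectory_averaged_connectivity,
                                 weighted_out_degree)
from emadyn.models import StaticBaseline, VAR1Forecaster

from conftest import make_plrnn_model, random_plrnn_model


def test_scalar_kalman_connectivity_closed_form():
    # a=0.5, b=1, q=0.75, gamma=0: Szz = q/(1-a^2) = 1, G = 1/(1+0) = 1,
    # W = b a G = 0.5
    W = connectivity_kalman(np.array([[0.5]]), np.array([[1.0]]),
                            np.array([[0.75]]), np.array([[0.0]])).W
    assert W[0, 0] == pytest.approx(0.5)


def test_recognition_gain_kalman_matches_lyapunov_solution(small_ssm):
    A, B, Q, Gam = (small_ssm[k] for k in ("A", "B", "Q", "Gamma"))
    G = recognition_gain_kalman(A, B, Q, Gam)
    Szz = linalg.solve_discrete_lyapunov(A, Q)
    expected = Szz @ B.T @ np.linalg.inv(B @ Szz @ B.T + Gam)
    assert np.allclose(G, expected)


def test_recognition_gain_kalman_rejects_unstable_A():
    with pytest.raises(ValueError, match="unstable"):
        recognition_gain_kalman(np.eye(2) * 1.2, np.eye(2), np.eye(2), np.eye(2))


def test_recognition_gain_plrnn_is_left_inverse():
    rng = np.random.default_rng(0)
    B = rng.normal(size=(6, 3))
    Gam = np.diag(rng.uniform(0.1, 1.0, size=6))
    G = recognition_gain_plrnn(B, Gam)
    assert np.allclose(G @ B, np.eye(3), atol=1e-10)


def test_var_connectivity_is_coefficient_matrix():
    A = np.array([[0.5, 0.1], [0.0, 0.6]])
    cm = connectivity_var(A)
    assert np.array_equal(cm.W, A)
    A[0, 0] = 99.0  # must have been copied
    assert cm.W[0, 0] == 0.5


def test_plrnn_local_jacobian_finite_difference():
    rng = np.random.default_rng(1)
    m = random_plrnn_model(rng)
    z = rng.normal(size=4)

    def f(z):
        pre = m.W2_ @ z
        return m.A_ @ z + m.W1_ @ (np.maximum(pre + m.b_, 0)
                                   - np.maximum(pre, 0)) + m.h_

    J = plrnn_local_jacobian(m.A_, m.W1_, m.W2_, m.b_, z)
    eps = 1e-7
    for k in range(4):
        dz = np.zeros(4); dz[k] = eps
        num = (f(z + dz) - f(z - dz)) / (2 * eps)
        assert np.allclose(J[:, k], num, atol=1e-5)


def test_connectivity_plrnn_composition():
    rng = np.random.default_rng(2)
    m = random_plrnn_model(rng)
    x = rng.normal(size=5)
    cm = connectivity_plrnn(m.A_, m.W1_, m.W2_, m.b_, m.B_, m.Gamma_, x)
    G = recognition_gain_plrnn(m.B_, m.Gamma_)
    J = plrnn_local_jacobian(m.A_, m.W1_, m.W2_, m.b_, G @ x)
    assert np.allclose(cm.W, m.B_ @ J @ G)


def test_connectivity_dispatch_and_rejections():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 3))
    var = VAR1Forecaster().fit(X)
    assert connectivity(var).model == "var"
    m = random_plrnn_model(rng)
    with pytest.raises(ValueError, match="state dependent"):
        connectivity(m)
    static = StaticBaseline().fit(X)
    with pytest.raises(TypeError, match="network"):
        connectivity(static)


def test_trajectory_average_equals_single_point_for_linear_model():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(50, 3))
    var = VAR1Forecaster().fit(X)
    cm = trajectory_averaged_connectivity([var], X[:10])
    assert np.allclose(cm.W, var.A_)
    assert cm.aggregation == "trajectory_mean"


def test_group_edge_significance_detects_consistent_edge():
    rng = np.random.default_rng(5)
    mats = [np.eye(3) * 0.5 + rng.normal(0, 0.01, size=(3, 3))
            for _ in range(10)]
    df = group_edge_significance(mats)
    diag = df[(df.source == df.target)]
    off = df[(df.source == 0) & (df.target == 1)]
    assert diag["significant"].all()
    assert not off["significant"].iloc[0]
    with pytest.raises(ValueError, match="three"):
        group_edge_significance(mats[:2])


def test_weighted_out_degree_excludes_self_loops():
    W = np.array([[9.0, 2.0], [-1.0, 9.0]])
    scores = weighted_out_degree(W)
    assert np.allclose(scores.out_degree, [1.0, 2.0])
    assert scores.ranks.tolist() == [1.0, 2.0]
    with_self = weighted_out_degree(W, include_self=True)
    assert np.allclose(with_self.out_degree, [10.0, 11.0])


def test_lyapunov_exponent_of_linear_contraction():
    # z_{t+1} = 0.5 z_t: exponent exactly ln 0.5
    var = VAR1Forecaster()
    var.A_ = np.diag([0.5, 0.2])
    var.h_ = np.zeros(2)
    lam = lyapunov_qr(var, n_steps=2000, n_discard=100)
    assert lam == pytest.approx(np.log(0.5), abs=1e-9)


def test_lyapunov_plrnn_matches_qr_over_known_jacobians():
    rng = np.random.default_rng(6)
    m = random_plrnn_model(rng)
    lam = lyapunov_qr(m, z0=rng.normal(size=4), n_steps=3000, n_discard=300)
    assert np.isfinite(lam)
    assert lam < 0  # contractive construction (|a| < 0.8, small W)


def test_lyapunov_validates_arguments():
    var = VAR1Forecaster()
    var.A_ = np.array([[0.5]])
    var.h_ = np.zeros(1)
    with pytest.raises(ValueError, match="exceed"):
        lyapunov_qr(var, n_steps=10, n_discard=10)


def test_connectivity_matrix_validation():
    with pytest.raises(ValueError, match="square"):
        ConnectivityMatrix(W=np.zeros((2, 3)))
    with pytest.raises(ValueError, match="finite"):
        ConnectivityMatrix(W=np.array([[np.inf]]))
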