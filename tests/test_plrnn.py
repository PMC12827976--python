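"""Shallow PLRNN with generalized teacher forcing."""

import numpy as np
import pytest

from emadyn.models import KalmanForecaster, PLRNNForecaster
from emadyn.synthetic import GroundTruthModel, simulate_continuous

from conftest import make_plrnn_model, random_plrnn_model


def test_latent_step_matches_equation():
    rng = np.random.default_rng(0)
    m = random_plrnn_model(rng)
    z = rng.normal(size=4)
    u = rng.normal(size=3)
    pre = m.W2_ @ z
    expected = (m.A_ @ z
                + m.W1_ @ (np.maximum(pre + m.b_, 0) - np.maximum(pre, 0))
                + m.h_ + m.C_ @ u)
    assert np.allclose(m.latent_step(z, u), expected)


def test_zero_w1_reduces_to_linear_ssm_rollout():
    """With W1 = 0 the PLRNN transition is exactly the linear SSM transition."""
    rng = np.random.default_rng(1)
    l, n, mm = 3, 4, 2
    A = np.diag([0.5, 0.7, 0.3])
    C = rng.normal(size=(l, mm))
    B = rng.normal(size=(n, l))
    h = rng.normal(size=l)
    pl = make_plrnn_model(A, np.zeros((l, 5)), rng.normal(size=(5, l)),
                          rng.normal(size=5), h, C, B)
    kf = KalmanForecaster(latent_dim=l)
    kf.A_, kf.C_, kf.h_, kf.B_ = A, C, h, B
    kf.n_items_, kf.n_inputs_ = n, mm
    kf.z_last_ = np.zeros(l)
    Uf = (rng.random((6, mm)) < 0.5).astype(float)
    assert np.allclose(pl.predict(U_future=Uf, horizon=6),
                       kf.predict(U_future=Uf, horizon=6))


def test_training_reduces_loss_and_is_seed_deterministic():
    rng = np.random.default_rng(2)
    truth = GroundTruthModel(
        family="var", latent_dim=3, A=np.diag([0.8, 0.6, 0.7]),
        C=np.zeros((3, 1)), B=rng.normal(size=(4, 3)), h=np.zeros(3),
        process_noise_sd=0.5, obs_noise_sd=0.1)
    X, U = simulate_continuous(truth, T=150, seed=3)
    kw = dict(latent_dim=3, hidden_dim=8, epochs=30, lr=5e-3, random_state=7)
    m1 = PLRNNForecaster(**kw).fit(X, U)
    assert m1.loss_curve_[-1] < m1.loss_curve_[0]
    m2 = PLRNNForecaster(**kw).fit(X, U)
    assert np.allclose(m1.W1_, m2.W1_)
    assert np.allclose(m1.predict(horizon=3), m2.predict(horizon=3))


def test_fit_handles_missing_cells():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(100, 4))
    X[rng.random((100, 4)) < 0.3] = np.nan
    X[10] = np.nan  # a fully missing row
    m = PLRNNForecaster(latent_dim=3, hidden_dim=6, epochs=5,
                        random_state=0).fit(X)
    assert np.all(np.isfinite(m.predict(horizon=5)))
    assert np.all(np.diag(m.Gamma_) > 0)


def test_gtf_alpha_bounds_validated():
    with pytest.raises(ValueError, match="gtf_alpha"):
        PLRNNForecaster(gtf_alpha=1.5).fit(np.zeros((10, 2)))
    with pytest.raises(ValueError, match="seq_len"):
        PLRNNForecaster(seq_len=1).fit(np.zeros((10, 2)))
    with pytest.raises(ValueError, match="connectivity"):
        PLRNNForecaster(connectivity="sparse", epochs=1).fit(
            np.random.default_rng(0).normal(size=(20, 2)))


def test_dense_connectivity_learns_full_matrix():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(60, 3))
    m = PLRNNForecaster(latent_dim=3, hidden_dim=4, epochs=3,
                        connectivity="dense", random_state=0).fit(X)
    offdiag = m.A_ - np.diag(np.diag(m.A_))
    assert np.any(offdiag != 0)


def test_diag_connectivity_keeps_A_diagonal():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(60, 3))
    m = PLRNNForecaster(latent_dim=3, hidden_dim=4, epochs=3,
                        random_state=0).fit(X)
    assert np.allclose(m.A_, np.diag(np.diag(m.A_)))


def test_plrnn_gradients_match_finite_differences():
    """End-to-end training-loss gradient vs central differences (small net)."""
    from emadyn._autograd import Tensor, relu

    rng = np.random.default_rng(7)
    l, H, n, mm, T = 2, 3, 2, 1, 5
    X = rng.normal(size=(T, n))
    U = (rng.random((T, mm)) < 0.5).astype(float)
    names = ["a", "W1", "W2", "b", "h", "C", "B"]
    shapes = [(l,), (l, H), (H, l), (H,), (l,), (l, mm), (n, l)]
    vals = {k: rng.normal(0, 0.5, size=s) for k, s in zip(names, shapes)}

    def loss_fn(vals):
        P = {k: Tensor(v.copy()) for k, v in vals.items()}
        Bpinv = np.linalg.pinv(P["B"].data)
        z = Tensor((X[0] @ Bpinv.T)[None, :], requires_grad=False)
        loss = None
        alpha = 0.2
        for t in range(1, T):
            pre = z @ P["W2"].T
            phi = relu(pre + P["b"]) - relu(pre)
            zbar = z * P["a"] + phi @ P["W1"].T + P["h"] \
                + Tensor(U[t - 1:t], requires_grad=False) @ P["C"].T
            xhat = zbar @ P["B"].T
            sq = ((xhat - Tensor(X[t:t + 1], requires_grad=False)) ** 2).sum()
            loss = sq if loss is None else loss + sq
            zd = Tensor((X[t] @ Bpinv.T)[None, :], requires_grad=False)
            z = zbar + (zd - zbar) * alpha
        return loss, P

    loss, P = loss_fn(vals)
    loss.backward()
    eps = 1e-6
    for k in ["a", "W1", "b", "C"]:  # spot-check a subset of parameters
        g_num = np.zeros_like(vals[k])
        it = np.nditer(vals[k], flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            vp = {kk: v.copy() for kk, v in vals.items()}
            vm = {kk: v.copy() for kk, v in vals.items()}
            vp[k][i] += eps
            vm[k][i] -= eps
            g_num[i] = (loss_fn(vp)[0].data - loss_fn(vm)[0].data) / (2 * eps)
        assert np.allclose(P[k].grad, g_num, atol=1e-4), k


def test_predict_respects_inputs():
    rng = np.random.default_rng(8)
    m = random_plrnn_model(rng)
    Uf0 = np.zeros((3, 3))
    Uf1 = np.zeros((3, 3)); Uf1[0, 1] = 1.0
    p0 = m.predict(U_future=Uf0, horizon=3)
    p1 = m.predict(U_future=Uf1, horizon=3)
    assert not np.allclose(p0, p1)
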