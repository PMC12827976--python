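"""Observation-space effective connectivity, centrality and stability.

Connectivity is the Jacobian of the one-step conditional expectation
E[x_t | x_{t-1} = x] with respect to x; entry (j, i) quantifies the influence
of item i on item j. For a VAR this is the coefficient matrix itself; for the
linear state-space model it is B A G_KF with the stationary-Gaussian
recognition gain G_KF = Sigma_zx Sigma_xx^-1; for the piecewise-linear RNN it
is B J G_RNN with the local Jacobian J of the active linear region and the
generalized-least-squares gain G_RNN = (B' Gam^-1 B)^-1 B' Gam^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .models import (KalmanForecaster, PLRNNForecaster, StaticBaseline,
                     TransformerForecaster, VAR1Forecaster)

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix", "CentralityScores", "connectivity_var",
    "connectivity_kalman", "connectivity_plrnn", "connectivity",
    "trajectory_averaged_connectivity", "group_edge_significance",
    "weighted_out_degree", "lyapunov_qr", "recognition_gain_kalman",
    "recognition_gain_plrnn",
]


@dataclass
class ConnectivityMatrix:
    """n x n effective connectivity; W[j, i] = influence of item i on item j."""

    W: np.ndarray
    model: str = ""
    aggregation: str = "local"   # local | trajectory_mean | group_mean

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("connectivity must be square")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("connectivity entries must be finite")

    def to_frame(self, item_names=None) -> pd.DataFrame:
        names = item_names or [f"item_{i}" for i in range(self.W.shape[0])]
        return pd.DataFrame(self.W, index=names, columns=names)


@dataclass
class CentralityScores:
    out_degree: np.ndarray
    ranks: np.ndarray            # 1 = lowest centrality (rank grows with degree)


# --------------------------------------------------------------------------
# recognition gains
# --------------------------------------------------------------------------

def recognition_gain_kalman(A: np.ndarray, B: np.ndarray, Q: np.ndarray,
                            Gamma: np.ndarray) -> np.ndarray:
    """Stationary posterior sensitivity of z to x: Sigma_zx Sigma_xx^-1.

    The latent covariance solves the discrete Lyapunov equation
    Sigma_zz = A Sigma_zz A' + Q.
    """
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    if rho >= 1.0:
        raise ValueError(f"transition matrix unstable (spectral radius {rho:.3f})")
    Szz = linalg.solve_discrete_lyapunov(A, Q)
    Szx = Szz @ B.T
    Sxx = B @ Szz @ B.T + Gamma
    try:
        return np.linalg.solve(Sxx.T, Szx.T).T
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(Sxx) / Sxx.shape[0]
        logger.warning("singular observation covariance; adding jitter %.2e", jitter)
        return Szx @ np.linalg.inv(Sxx + jitter * np.eye(Sxx.shape[0]))


def recognition_gain_plrnn(B: np.ndarray, Gamma: np.ndarray) -> np.ndarray:
    """GLS estimator of z from x: (B' Gam^-1 B)^-1 B' Gam^-1 (flat prior on z)."""
    try:
        Gi = np.linalg.inv(Gamma)
    except np.linalg.LinAlgError:
        Gi = np.linalg.pinv(Gamma)
    M = B.T @ Gi @ B
    try:
        return np.linalg.solve(M, B.T @ Gi)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(M) @ B.T @ Gi


# --------------------------------------------------------------------------
# per-family connectivity
# --------------------------------------------------------------------------

def connectivity_var(A: np.ndarray) -> ConnectivityMatrix:
    """The VAR(1) Jacobian is the coefficient matrix itself."""
    return ConnectivityMatrix(W=np.array(A, dtype=float, copy=True), model="var")


def connectivity_kalman(A: np.ndarray, B: np.ndarray, Q: np.ndarray,
                        Gamma: np.ndarray) -> ConnectivityMatrix:
    G = recognition_gain_kalman(A, B, Q, Gamma)
    return ConnectivityMatrix(W=B @ A @ G, model="kalman")


def plrnn_local_jacobian(A: np.ndarray, W1: np.ndarray, W2: np.ndarray,
                         b: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Latent Jacobian of the shallow-PLRNN map in the linear region of z.

    States exactly on a switching boundary use the open half-space convention
    (strict >), which makes the choice deterministic.
    """
    pre = W2 @ z
    d = (pre + b > 0).astype(float) - (pre > 0).astype(float)
    return A + W1 @ (d[:, None] * W2)


def connectivity_plrnn(A: np.ndarray, W1: np.ndarray, W2: np.ndarray,
                       b: np.ndarray, B: np.ndarray, Gamma: np.ndarray,
                       x: np.ndarray) -> ConnectivityMatrix:
    G = recognition_gain_plrnn(B, Gamma)
    z = G @ np.asarray(x, dtype=float)
    J = plrnn_local_jacobian(A, W1, W2, b, z)
    return ConnectivityMatrix(W=B @ J @ G, model="plrnn")


def connectivity(model, x: np.ndarray | None = None) -> ConnectivityMatrix:
    """Dispatch on a fitted forecaster; ``x`` is required for the PLRNN."""
    if isinstance(model, VAR1Forecaster):
        return connectivity_var(model.A_)
    if isinstance(model, KalmanForecaster):
        return connectivity_kalman(model.A_, model.B_, model.Q_, model.Gamma_)
    if isinstance(model, PLRNNForecaster):
        if x is None:
            raise ValueError("PLRNN connectivity is state dependent; pass x")
        return connectivity_plrnn(model.A_, model.W1_, model.W2_, model.b_,
                                  model.B_, model.Gamma_, x)
    if isinstance(model, (TransformerForecaster, StaticBaseline)):
        raise TypeError(f"{type(model).__name__} does not define an "
                        "interpretable item-level network")
    raise TypeError(f"unsupported model type {type(model).__name__}")


def trajectory_averaged_connectivity(models: list, X: np.ndarray) -> ConnectivityMatrix:
    """Connectivity at every observed point, averaged over time then members.

    ``X`` is the (possibly missing) observation trajectory on the centered
    scale; rows with no observed item are skipped. Linear models are
    state independent, so their average equals the single-point matrix.
    """
    if not models:
        raise ValueError("need at least one model")
    X = np.asarray(X, dtype=float)
    rows = [t for t in range(X.shape[0]) if not np.isnan(X[t]).all()]
    if not rows:
        raise ValueError("empty trajectory: no observed points")
    mats = []
    for model in models:
        if isinstance(model, PLRNNForecaster):
            pts = [connectivity(model, np.nan_to_num(X[t])).W for t in rows]
            mats.append(np.mean(pts, axis=0))
        else:
            mats.append(connectivity(model).W)
    tag = type(models[0]).__name__
    return ConnectivityMatrix(W=np.mean(mats, axis=0), model=tag,
                              aggregation="trajectory_mean")


# --------------------------------------------------------------------------
# group statistics and centrality
# --------------------------------------------------------------------------

def group_edge_significance(matrices: list, alpha: float = 0.01) -> pd.DataFrame:
    """One-sample t-test per edge across subjects, Bonferroni factor n^2.

    Returns an edge list (source, target, mean, t, p, p_bonf, significant);
    orientation follows W[target, source].
    """
    if len(matrices) < 3:
        raise ValueError("need at least three subjects")
    Ws = np.array([m.W if isinstance(m, ConnectivityMatrix) else m
                   for m in matrices])
    n = Ws.shape[1]
    n_comp = n * n
    rows = []
    for j in range(n):
        for i in range(n):
            vals = Ws[:, j, i]
            sd = vals.std(ddof=1)
            if sd == 0:
                t, p = (np.inf, 0.0) if vals.mean() != 0 else (0.0, 1.0)
            else:
                t, p = stats.ttest_1samp(vals, 0.0)
            p_bonf = min(float(p) * n_comp, 1.0)
            rows.append({"source": i, "target": j, "mean": float(vals.mean()),
                         "t": float(t), "p": float(p), "p_bonf": p_bonf,
                         "significant": bool(p_bonf < alpha)})
    return pd.DataFrame(rows)


def weighted_out_degree(W, include_self: bool = False) -> CentralityScores:
    """Total absolute outgoing edge weight per node (column sums of |W|)."""
    W = W.W if isinstance(W, ConnectivityMatrix) else np.asarray(W, dtype=float)
    absW = np.abs(W).copy()
    if not include_self:
        np.fill_diagonal(absW, 0.0)
    deg = absW.sum(axis=0)
    ranks = stats.rankdata(deg, method="average")
    return CentralityScores(out_degree=deg, ranks=ranks)


# --------------------------------------------------------------------------
# Lyapunov exponent
# --------------------------------------------------------------------------

def lyapunov_qr(model, z0: np.ndarray | None = None, n_steps: int = 10_000,
                n_discard: int = 1_000, divergence_bound: float = 1e8) -> float:
    """Maximal Lyapunov exponent of the autonomous latent dynamics by the
    QR method: accumulate log of the leading R diagonal of successively
    re-orthonormalized Jacobian products after discarding transients."""
    if n_steps <= n_discard:
        raise ValueError("n_steps must exceed n_discard")
    if isinstance(model, PLRNNForecaster) or hasattr(model, "W1_"):
        A, W1, W2, b, h = model.A_, model.W1_, model.W2_, model.b_, model.h_

        def step(z):
            pre = W2 @ z
            return A @ z + W1 @ (np.maximum(pre + b, 0) - np.maximum(pre, 0)) + h

        def jac(z):
            return plrnn_local_jacobian(A, W1, W2, b, z)
    elif isinstance(model, (VAR1Forecaster, KalmanForecaster)):
        A, h = model.A_, model.h_

        def step(z):
            return A @ z + h

        def jac(z):
            return A
    else:
        raise TypeError("lyapunov_qr needs a model with explicit dynamics")

    l = model.A_.shape[0]
    z = np.zeros(l) if z0 is None else np.asarray(z0, dtype=float).copy()
    Qm = np.eye(l)
    acc = 0.0
    count = 0
    for t in range(n_steps):
        if not np.all(np.isfinite(z)) or np.max(np.abs(z)) > divergence_bound:
            raise ValueError("trajectory diverged during Lyapunov estimation")
        J = jac(z)
        Qm, R = np.linalg.qr(J @ Qm)
        # fix sign convention so diag(R) > 0
        s = np.sign(np.diag(R))
        s[s == 0] = 1.0
        Qm *= s
        if t >= n_discard:
            acc += np.log(np.abs(R[0, 0]) + 1e-300)
            count += 1
        z = step(z)
    return acc / count
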