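"""Linear-Gaussian state-space model (Kalman filter) fitted by EM.

    z_t = A z_{t-1} + C u_{t-1} + h + w_t,   w_t ~ N(0, Q)
    x_t = B z_t + v_t,                        v_t ~ N(0, Gamma)

Missing observation cells are handled exactly by row-reducing the observation
model at each filter step (only the observed components enter the update).
The E-step is the Kalman filter/RTS smoother, the M-step uses closed-form
updates; A is rescaled to spectral radius <= 1 - margin whenever an update
leaves the stable region. Several random initializations are fitted and the
best by log-likelihood kept; non-convergence is flagged, not hidden.
"""

from __future__ import annotations

import numpy as np

from ._base import BaseForecaster


def _sym(M):
    return 0.5 * (M + M.T)


class KalmanForecaster(BaseForecaster):
    """EM-fitted linear SSM.

    Fitted attributes: ``A_, C_, h_, B_, Q_, Gamma_`` (observation covariance,
    diagonal), ``mu0_, V0_``, ``loglik_curve_`` for the winning initialization,
    ``converged_`` and ``z_last_`` (filtered state at the end of training).
    """

    def __init__(self, latent_dim: int = 10, n_init: int = 5, max_iter: int = 500,
                 tol: float = 1e-6, stability_margin: float = 1e-3,
                 fix_B_identity: bool = False, random_state: int = 0):
        self.latent_dim = latent_dim
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.stability_margin = stability_margin
        self.fix_B_identity = fix_B_identity
        self.random_state = random_state

    # ------------------------------------------------------------------ E-step
    def _filter(self, X, U, A, C, h, B, Q, gam, mu0, V0):
        """Kalman filter with per-row missing-cell reduction.

        Returns filtered means/covs, predicted means/covs and log-likelihood.
        """
        T, n = X.shape
        l = A.shape[0]
        mf = np.zeros((T, l)); Vf = np.zeros((T, l, l))
        mp = np.zeros((T, l)); Vp = np.zeros((T, l, l))
        ll = 0.0
        for t in range(T):
            if t == 0:
                mpred, Ppred = mu0, V0
            else:
                mpred = A @ mf[t - 1] + C @ U[t - 1] + h
                Ppred = _sym(A @ Vf[t - 1] @ A.T + Q)
            mp[t], Vp[t] = mpred, Ppred
            obs = ~np.isnan(X[t])
            if not obs.any():
                mf[t], Vf[t] = mpred, Ppred
                continue
            Bo = B[obs]
            S = Bo @ Ppred @ Bo.T + np.diag(gam[obs])
            S = _sym(S) + 1e-10 * np.eye(obs.sum())
            innov = X[t, obs] - Bo @ mpred
            Sinv = np.linalg.inv(S)
            K = Ppred @ Bo.T @ Sinv
            mf[t] = mpred + K @ innov
            Vf[t] = _sym((np.eye(l) - K @ Bo) @ Ppred)
            sign, logdet = np.linalg.slogdet(S)
            ll += -0.5 * (obs.sum() * np.log(2 * np.pi) + logdet
                          + innov @ Sinv @ innov)
        return mf, Vf, mp, Vp, ll

    def _smooth(self, mf, Vf, mp, Vp, A):
        T, l = mf.shape
        ms = mf.copy(); Vs = Vf.copy()
        Vlag = np.zeros((T, l, l))  # Cov(z_t, z_{t-1} | all data), index t >= 1
        for t in range(T - 2, -1, -1):
            J = Vf[t] @ A.T @ np.linalg.inv(Vp[t + 1] + 1e-10 * np.eye(l))
            ms[t] = mf[t] + J @ (ms[t + 1] - mp[t + 1])
            Vs[t] = _sym(Vf[t] + J @ (Vs[t + 1] - Vp[t + 1]) @ J.T)
            Vlag[t + 1] = Vs[t + 1] @ J.T
        return ms, Vs, Vlag

    # ------------------------------------------------------------------ M-step
    def _mstep(self, X, U, ms, Vs, Vlag, B, gam):
        T, n = X.shape
        l = ms.shape[1]
        m_in = U.shape[1]
        d = l + m_in + 1
        S_ww = np.zeros((d, d)); S_zw = np.zeros((l, d)); S_zz = np.zeros((l, l))
        for t in range(1, T):
            Ez1 = ms[t - 1]
            Ezz1 = Vs[t - 1] + np.outer(Ez1, Ez1)
            w_mean = np.concatenate([Ez1, U[t - 1], [1.0]])
            S_ww += np.outer(w_mean, w_mean)
            S_ww[:l, :l] += Vs[t - 1]
            Ez = ms[t]
            Ezz_lag = Vlag[t] + np.outer(Ez, Ez1)
            S_zw[:, :l] += Ezz_lag
            S_zw[:, l:l + m_in] += np.outer(Ez, U[t - 1])
            S_zw[:, -1] += Ez
            S_zz += Vs[t] + np.outer(Ez, Ez)
        beta = S_zw @ np.linalg.inv(S_ww + 1e-8 * np.eye(d))
        A = beta[:, :l]; C = beta[:, l:l + m_in]; h = beta[:, -1]
        Q = _sym((S_zz - beta @ S_zw.T) / (T - 1))
        # keep Q positive definite
        ev, evec = np.linalg.eigh(Q)
        Q = evec @ np.diag(np.maximum(ev, 1e-8)) @ evec.T
        # stability projection
        rho = np.max(np.abs(np.linalg.eigvals(A)))
        if rho >= 1.0 - self.stability_margin:
            A = A * (1.0 - self.stability_margin) / rho

        # observation model, per item over observed cells
        Ezz_all = np.array([Vs[t] + np.outer(ms[t], ms[t]) for t in range(T)])
        if self.fix_B_identity:
            Bnew = B
        else:
            Bnew = np.zeros_like(B)
            for i in range(n):
                rows = ~np.isnan(X[:, i])
                if rows.sum() == 0:
                    Bnew[i] = B[i]
                    continue
                G = Ezz_all[rows].sum(axis=0)
                rhs = (X[rows, i][:, None] * ms[rows]).sum(axis=0)
                Bnew[i] = np.linalg.solve(G + 1e-8 * np.eye(l), rhs)
        gam_new = np.empty(n)
        for i in range(n):
            rows = ~np.isnan(X[:, i])
            if rows.sum() == 0:
                gam_new[i] = gam[i]
                continue
            xi = X[rows, i]
            resid2 = (xi**2 - 2 * xi * (ms[rows] @ Bnew[i])
                      + np.einsum("j,tjk,k->t", Bnew[i], Ezz_all[rows], Bnew[i]))
            gam_new[i] = max(np.mean(resid2), 1e-6)
        return A, C, h, Bnew, Q, gam_new

    # --------------------------------------------------------------------- fit
    def fit(self, X, U=None):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        X, U = self._validate(X, U)
        T, n = X.shape
        l = self.latent_dim
        if self.fix_B_identity and l != n:
            raise ValueError("fix_B_identity requires latent_dim == n_items")
        rng = np.random.default_rng(self.random_state)
        best = None
        self.init_converged_ = []
        for init in range(self.n_init):
            A = rng.normal(0, 1, size=(l, l))
            A *= 0.5 / max(np.max(np.abs(np.linalg.eigvals(A))), 1e-8)
            B = np.eye(n) if self.fix_B_identity else rng.normal(0, 1 / np.sqrt(l), size=(n, l))
            C = np.zeros((l, U.shape[1]))
            h = np.zeros(l)
            Q = np.eye(l) * 0.5
            gam = np.full(n, np.nanvar(X) + 1e-3)
            mu0 = np.zeros(l); V0 = np.eye(l)
            lls = []
            converged = False
            for it in range(self.max_iter):
                mf, Vf, mp, Vp, ll = self._filter(X, U, A, C, h, B, Q, gam, mu0, V0)
                lls.append(ll)
                ms, Vs, Vlag = self._smooth(mf, Vf, mp, Vp, A)
                A, C, h, B, Q, gam = self._mstep(X, U, ms, Vs, Vlag, B, gam)
                mu0 = ms[0]; V0 = _sym(Vs[0]) + 1e-8 * np.eye(l)
                if it > 0 and abs(lls[-1] - lls[-2]) < self.tol * (abs(lls[-2]) + 1.0):
                    converged = True
                    break
            mf, Vf, mp, Vp, ll = self._filter(X, U, A, C, h, B, Q, gam, mu0, V0)
            lls.append(ll)
            self.init_converged_.append(converged)
            if best is None or ll > best[0]:
                best = (ll, A, C, h, B, Q, gam, mu0, V0, lls, mf[-1], converged)
        (self.loglik_, self.A_, self.C_, self.h_, self.B_, self.Q_, gam,
         self.mu0_, self.V0_, self.loglik_curve_, self.z_last_,
         self.converged_) = best
        self.Gamma_ = np.diag(gam)
        self.n_items_, self.n_inputs_ = n, U.shape[1]
        return self

    # ----------------------------------------------------------------- predict
    def latent_step(self, z: np.ndarray, u: np.ndarray) -> np.ndarray:
        return self.A_ @ z + self.C_ @ u + self.h_

    def predict(self, U_future=None, horizon: int = 7) -> np.ndarray:
        U_future = self._future_inputs(U_future, horizon, self.n_inputs_)
        z = self.z_last_.copy()
        preds = np.empty((horizon, self.n_items_))
        for k in range(horizon):
            z = self.latent_step(z, U_future[k])
            preds[k] = self.B_ @ z
        return preds
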