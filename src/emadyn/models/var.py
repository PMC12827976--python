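"""First-order vector autoregression with ridge-stabilized dynamics.

x_t = A x_{t-1} + C u_{t-1} + h + eps_t, fitted by ridge regression with the
penalty applied to the dynamics coefficients A only. If the fitted A is
unstable (spectral radius >= 1) the penalty is increased on a geometric
schedule until stability holds, following the constraint that forecasts must
not diverge.
"""

from __future__ import annotations

import numpy as np

from ._base import BaseForecaster


class VAR1Forecaster(BaseForecaster):
    """VAR(1) with inputs; fitted attributes ``A_``, ``C_``, ``h_``, ``ridge_``."""

    def __init__(self, ridge: float = 1e-2, stability_margin: float = 1e-6,
                 ridge_growth: float = 10.0, max_ridge: float = 1e12):
        self.ridge = ridge
        self.stability_margin = stability_margin
        self.ridge_growth = ridge_growth
        self.max_ridge = max_ridge

    def fit(self, X, U=None):
        if self.ridge < 0:
            raise ValueError("ridge must be nonnegative")
        X, U = self._validate(X, U)
        T, n = X.shape
        m = U.shape[1]
        # transitions with both endpoints fully observed
        ok = ~np.isnan(X).any(axis=1)
        pairs = np.where(ok[:-1] & ok[1:])[0]
        if pairs.size < 2:
            raise ValueError("need at least two complete consecutive transitions")
        Z = np.concatenate([X[pairs], U[pairs], np.ones((pairs.size, 1))], axis=1)
        Y = X[pairs + 1]

        lam = self.ridge
        ZtZ, ZtY = Z.T @ Z, Z.T @ Y
        pen_mask = np.zeros(Z.shape[1])
        pen_mask[:n] = 1.0  # penalize only the A block
        while True:
            beta = np.linalg.solve(ZtZ + lam * np.diag(pen_mask)
                                   + 1e-10 * np.eye(Z.shape[1]), ZtY)
            A = beta[:n].T
            rho = np.max(np.abs(np.linalg.eigvals(A)))
            if rho < 1.0 - self.stability_margin or lam >= self.max_ridge:
                break
            lam = max(lam, 1e-4) * self.ridge_growth
        if rho >= 1.0:
            # last resort: shrink toward stability explicitly
            A = A * (1.0 - self.stability_margin) / rho
        self.A_ = A
        self.C_ = beta[n:n + m].T
        self.h_ = beta[n + m]
        self.ridge_ = lam
        self.n_items_, self.n_inputs_ = n, m
        # context for forecasting: the last fully observed row
        last = np.where(ok)[0][-1]
        self.x_last_ = X[last].copy()
        return self

    def predict(self, U_future=None, horizon: int = 7) -> np.ndarray:
        U_future = self._future_inputs(U_future, horizon, self.n_inputs_)
        x = self.x_last_.copy()
        preds = np.empty((horizon, self.n_items_))
        for k in range(horizon):
            x = self.A_ @ x + self.C_ @ U_future[k] + self.h_
            preds[k] = x
        return preds

    def predict_from(self, x0: np.ndarray, U_future=None, horizon: int = 7) -> np.ndarray:
        """Roll out from an explicit context point instead of the training tail."""
        U_future = self._future_inputs(U_future, horizon, self.n_inputs_)
        x = np.asarray(x0, dtype=float).copy()
        preds = np.empty((horizon, self.n_items_))
        for k in range(horizon):
            x = self.A_ @ x + self.C_ @ U_future[k] + self.h_
            preds[k] = x
        return preds
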