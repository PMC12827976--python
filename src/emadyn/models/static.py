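"""Non-dynamic baselines: persistence, global mean, input-only regression.

The persistence ("last step") model repeats the most recent observation; the
global-mean model predicts each item's training mean; the linear-regression
model x_t = C u_{t-1} + h predicts from intervention inputs alone, so any
temporal variation in its forecasts comes from time-varying inputs rather
than intrinsic dynamics.
"""

from __future__ import annotations

import numpy as np

from ._base import BaseForecaster

KINDS = ("last_step", "global_mean", "linear_regression")


class StaticBaseline(BaseForecaster):
    """Static predictor of one of the three baseline kinds.

    Attributes (after fit)
    ----------------------
    mu_ : per-item training mean (global_mean)
    x_last_ : per-item last observed value (last_step)
    C_, h_ : input map and intercept (linear_regression)
    """

    def __init__(self, kind: str = "last_step"):
        self.kind = kind

    def fit(self, X, U=None):
        if self.kind not in KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        X, U = self._validate(X, U)
        self.n_items_ = X.shape[1]
        self.n_inputs_ = U.shape[1]
        if self.kind == "last_step":
            # per-item most recent observed value
            x_last = np.full(X.shape[1], np.nan)
            for i in range(X.shape[1]):
                obs = np.where(~np.isnan(X[:, i]))[0]
                if obs.size == 0:
                    raise ValueError(f"item {i} has no observations")
                x_last[i] = X[obs[-1], i]
            self.x_last_ = x_last
        elif self.kind == "global_mean":
            self.mu_ = np.nanmean(X, axis=0)
        else:
            # x_t = C u_{t-1} + h, least squares per item over observed cells
            T, m = U.shape
            Z = np.concatenate([np.vstack([np.zeros(m), U[:-1]]),
                                np.ones((T, 1))], axis=1)
            C = np.zeros((X.shape[1], m))
            h = np.zeros(X.shape[1])
            for i in range(X.shape[1]):
                rows = ~np.isnan(X[:, i])
                beta, *_ = np.linalg.lstsq(Z[rows], X[rows, i], rcond=None)
                C[i] = beta[:m]
                h[i] = beta[m]
            self.C_, self.h_ = C, h
        return self

    def predict(self, U_future=None, horizon: int = 7) -> np.ndarray:
        U_future = self._future_inputs(U_future, horizon, self.n_inputs_)
        if self.kind == "last_step":
            return np.tile(self.x_last_, (horizon, 1))
        if self.kind == "global_mean":
            return np.tile(self.mu_, (horizon, 1))
        preds = np.empty((horizon, self.n_items_))
        for k in range(horizon):
            preds[k] = self.C_ @ U_future[k] + self.h_
        return preds
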