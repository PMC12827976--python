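"""Shared fit/forecast contract for the model ladder."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["BaseForecaster", "fit_ensemble", "ensemble_forecast", "rollout_forecast"]


class BaseForecaster(BaseEstimator):
    """Common interface: ``fit(X, U)`` then ``predict(U_future, horizon)``.

    ``X`` is a T x n centered observation matrix with NaN marking missing
    cells; ``U`` a T x m binary input matrix whose row t holds the inputs
    delivered right after observation t. The transition into forecast step k
    (k = 1..horizon) uses input row ``U_future[k-1]``, i.e. the input vector
    attached to observation tau+k-1, where tau is the last training row.
    """

    def fit(self, X, U=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, U_future=None, horizon: int = 7) -> np.ndarray:
        raise NotImplementedError

    # -- helpers shared by subclasses ------------------------------------
    @staticmethod
    def _validate(X, U):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty T x n matrix")
        if U is None:
            U = np.zeros((X.shape[0], 0))
        U = np.asarray(U, dtype=float)
        if U.shape[0] != X.shape[0]:
            raise ValueError("U must align row-wise with X")
        return X, U

    @staticmethod
    def _future_inputs(U_future, horizon, m):
        if horizon < 0:
            raise ValueError("horizon must be nonnegative")
        if U_future is None:
            U_future = np.zeros((horizon, m))
        U_future = np.asarray(U_future, dtype=float)
        if U_future.shape[0] < horizon:
            raise ValueError("U_future must provide at least `horizon` rows")
        if U_future.shape[1] != m:
            raise ValueError(f"U_future must have {m} input columns")
        return U_future


def rollout_forecast(model: BaseForecaster, U_future=None, horizon: int = 7) -> np.ndarray:
    """Iterate a fitted model's dynamics ``horizon`` steps (centered scale)."""
    return model.predict(U_future=U_future, horizon=horizon)


def fit_ensemble(factory, X, U=None, n_members: int = 10, seed: int = 0) -> list:
    """Fit ``n_members`` independently initialized copies of a model.

    ``factory(seed)`` must return an unfitted forecaster whose randomness is
    controlled by ``seed``. Member seeds derive deterministically from the
    master seed.
    """
    if n_members < 1:
        raise ValueError("ensemble needs at least one member")
    ss = np.random.SeedSequence(seed)
    members = []
    for child in ss.spawn(n_members):
        member_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        m = factory(member_seed)
        m.fit(X, U)
        members.append(m)
    return members


def ensemble_forecast(members: list, U_future=None, horizon: int = 7) -> np.ndarray:
    """Pointwise mean forecast across ensemble members."""
    if not members:
        raise ValueError("empty ensemble")
    preds = [m.predict(U_future=U_future, horizon=horizon) for m in members]
    return np.mean(preds, axis=0)
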