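"""Event-stream alignment, causal smoothing and train-statistics centering.

The modeling pipeline consumes an aligned pair (X, U): a T x n EMA matrix on
irregular timestamps and a binary T x m intervention-input matrix whose rows
correspond one-to-one with EMA rows. Interactive interventions delivered right
after a survey land on that survey's row; consolidation interventions are
assigned to the most recent preceding survey. Training data are smoothed with
a causal right-truncated Gaussian kernel and mean-centered with training-set
statistics; test data are centered with the same statistics but never
smoothed, preserving a strict train/test information barrier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["AlignedSeries", "SmoothingConfig", "build_matrices",
           "causal_smooth", "center_split", "decenter"]


@dataclass
class SmoothingConfig:
    """Causal Gaussian kernel parameters, in hours."""

    window: float = 4.0
    sigma: float = 1.5

    def __post_init__(self):
        if self.window <= 0 or self.sigma <= 0:
            raise ValueError("window and sigma must be positive")


@dataclass
class AlignedSeries:
    """Row-aligned observation/input matrices with timestamps (hours)."""

    X: np.ndarray                 # T x n, NaN = missing cell
    U: np.ndarray                 # T x m binary
    timestamps: np.ndarray        # T
    train_means: np.ndarray | None = None  # set by center_split

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.X.shape[0] != self.U.shape[0] or self.X.shape[0] != self.timestamps.size:
            raise ValueError("X, U and timestamps must agree on T")
        if not np.isin(self.U[~np.isnan(self.U)], (0.0, 1.0)).all():
            raise ValueError("U entries must be binary")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be nondecreasing")

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def n_items(self) -> int:
        return self.X.shape[1]

    def slice(self, idx) -> "AlignedSeries":
        return AlignedSeries(self.X[idx], self.U[idx], self.timestamps[idx],
                             train_means=self.train_means)


def build_matrices(events: pd.DataFrame,
                   item_names: Sequence[str] | None = None,
                   emi_names: Sequence[str] | None = None,
                   reversed_items: Sequence[str] = (),
                   recode_reversed: bool = True,
                   likert_min: int = 1, likert_max: int = 7):
    """Convert a long event table into an :class:`AlignedSeries`.

    Expects columns subject_id, timestamp_hours, event_type ('ema'|'emi'),
    item_or_emi_id, value. Any intervention event is assigned to the most
    recent preceding EMA row; interventions before the first EMA are dropped
    with a logged warning. Reverse-scored items are recoded to
    ``likert_min + likert_max - value`` so that higher always means better.

    Returns (aligned, meta) where meta carries item/EMI name order.
    """
    bad = set(events["event_type"]) - {"ema", "emi"}
    if bad:
        raise ValueError(f"unknown event type(s): {sorted(bad)}")
    ema_ev = events[events["event_type"] == "ema"]
    emi_ev = events[events["event_type"] == "emi"]

    if item_names is None:
        item_names = list(pd.unique(ema_ev["item_or_emi_id"]))
    if emi_names is None:
        emi_names = list(pd.unique(emi_ev["item_or_emi_id"]))
    item_idx = {name: i for i, name in enumerate(item_names)}
    emi_idx = {name: j for j, name in enumerate(emi_names)}

    ema_times = np.sort(pd.unique(ema_ev["timestamp_hours"]))
    T = ema_times.size
    X = np.full((T, len(item_names)), np.nan)
    U = np.zeros((T, max(len(emi_names), 1)))
    time_row = {t: r for r, t in enumerate(ema_times)}

    for t, name, v in zip(ema_ev["timestamp_hours"], ema_ev["item_or_emi_id"],
                          ema_ev["value"]):
        if name not in item_idx:
            continue
        val = float(v)
        if recode_reversed and name in set(reversed_items):
            val = likert_min + likert_max - val
        X[time_row[t], item_idx[name]] = val

    n_dropped = 0
    for t, name in zip(emi_ev["timestamp_hours"], emi_ev["item_or_emi_id"]):
        row = np.searchsorted(ema_times, t, side="right") - 1
        if row < 0:
            n_dropped += 1
            continue
        if name in emi_idx:
            U[row, emi_idx[name]] = 1.0
    if n_dropped:
        logger.warning("dropped %d EMI event(s) preceding the first EMA", n_dropped)

    U = U[:, :len(emi_names)] if emi_names else U[:, :0]
    aligned = AlignedSeries(X=X, U=U if U.shape[1] else np.zeros((T, 0)),
                            timestamps=ema_times)
    meta = {"item_names": list(item_names), "emi_names": list(emi_names)}
    return aligned, meta


def causal_smooth(X: np.ndarray, timestamps: np.ndarray,
                  cfg: SmoothingConfig | None = None) -> np.ndarray:
    """Right-truncated Gaussian smoothing over observed points only.

    The smoothed value at time t is the weighted mean of the observed values
    at times s in (t - window, t], with weights exp(-(t-s)^2 / (2 sigma^2))
    renormalized over the included points. Missing cells stay missing; a point
    with no observed neighbour in the window (itself included) is unchanged.
    Intended for training data only.
    """
    cfg = cfg or SmoothingConfig()
    X = np.asarray(X, dtype=float)
    ts = np.asarray(timestamps, dtype=float)
    out = np.full_like(X, np.nan)
    T = X.shape[0]
    for t in range(T):
        lo = ts[t] - cfg.window
        j0 = np.searchsorted(ts, lo, side="right")  # strictly inside (t-w, t]
        sl = slice(j0, t + 1)
        dt = ts[t] - ts[sl]
        w = np.exp(-dt**2 / (2.0 * cfg.sigma**2))
        block = X[sl]
        obs = ~np.isnan(block)
        for i in range(X.shape[1]):
            if np.isnan(X[t, i]):
                continue
            wi = w[obs[:, i]]
            out[t, i] = np.sum(wi * block[obs[:, i], i]) / np.sum(wi)
    return out


def center_split(train_X: np.ndarray, test_X: np.ndarray | None = None):
    """Subtract per-item training means from train (and optionally test).

    Returns (train_centered, test_centered, train_means); ``test_centered`` is
    None when no test matrix is given. Raises if any item is entirely missing
    in the training matrix.
    """
    train_X = np.asarray(train_X, dtype=float)
    n_obs = (~np.isnan(train_X)).sum(axis=0)
    if np.any(n_obs == 0):
        bad = np.where(n_obs == 0)[0].tolist()
        raise ValueError(f"item(s) {bad} fully missing in training data")
    means = np.nanmean(train_X, axis=0)
    train_c = train_X - means
    test_c = None
    if test_X is not None:
        test_c = np.asarray(test_X, dtype=float) - means
    return train_c, test_c, means


def decenter(X_centered: np.ndarray, train_means: np.ndarray) -> np.ndarray:
    """Invert :func:`center_split` (back to the absolute 1-7 scale)."""
    return np.asarray(X_centered, dtype=float) + np.asarray(train_means, dtype=float)
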