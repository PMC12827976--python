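"""Rolling-origin forecast evaluation with hierarchical MAE aggregation.

Mirrors a nightly-retraining deployment: for every eligible test day, all
data up to (and including) the day's first survey form the training set, and
the model forecasts the day's remaining observations (up to seven steps).
Absolute errors on the 1-7 scale are averaged items -> time points -> days ->
subject, so days with unequal numbers of surveys weigh equally. The module
also hosts the model-comparison statistics, the window/compliance ablation
and the per-item stationarity screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ensemble_forecast, fit_ensemble
from .preprocess import AlignedSeries, SmoothingConfig, causal_smooth, center_split, decenter
from .synthetic import SimulatedStudy

__all__ = [
    "ProtocolConfig", "SubjectEvaluation", "day_ids", "eligible_test_days",
    "rolling_origin_split", "mae_hierarchical", "mae_post_emi",
    "evaluate_subject", "compare_models", "run_data_ablation",
    "stationarity_classify",
]


@dataclass
class ProtocolConfig:
    """Rolling-origin protocol parameters (days are 1-based)."""

    first_eligible_day: int = 11
    min_ema_per_day: int = 3
    require_first_ema: bool = True
    horizon: int = 7
    ensemble_size: int = 10
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)

    def __post_init__(self):
        if min(self.first_eligible_day, self.min_ema_per_day, self.horizon,
               self.ensemble_size) < 1:
            raise ValueError("protocol counts must be positive")


@dataclass
class SubjectEvaluation:
    """Per-subject forecast accuracy summary."""

    per_day_mae: dict              # day id -> MAE
    overall_mae: float
    intervention_mae: float        # NaN when no post-EMI test point exists
    per_item_mae: np.ndarray
    eligible_days: list

    @property
    def has_intervention_points(self) -> bool:
        return np.isfinite(self.intervention_mae)


# --------------------------------------------------------------------------
# eligibility and splitting
# --------------------------------------------------------------------------

def day_ids(timestamps: np.ndarray) -> np.ndarray:
    """1-based study day of each row (day boundary at multiples of 24 h)."""
    return (np.asarray(timestamps, dtype=float) // 24.0).astype(int) + 1


def eligible_test_days(X: np.ndarray, timestamps: np.ndarray,
                       cfg: ProtocolConfig | None = None) -> list[int]:
    """Days usable for testing: late enough, enough completed surveys,
    and (optionally) a completed first survey of the day.

    A survey counts as completed when at least one item was answered.
    """
    cfg = cfg or ProtocolConfig()
    X = np.asarray(X, dtype=float)
    days = day_ids(timestamps)
    completed = ~np.isnan(X).all(axis=1)
    out = []
    for d in np.unique(days):
        if d < cfg.first_eligible_day:
            continue
        rows = np.where(days == d)[0]
        if completed[rows].sum() < cfg.min_ema_per_day:
            continue
        if cfg.require_first_ema and not completed[rows[0]]:
            continue
        out.append(int(d))
    return out


def rolling_origin_split(series: AlignedSeries, day: int,
                         cfg: ProtocolConfig | None = None):
    """Index split for test day ``day``: (train_rows, test_rows).

    The training set contains every row before the day plus the day's first
    survey (known at forecast time and used as context); the test set is the
    day's remaining rows. The two never overlap and jointly cover all rows up
    to the end of the day.
    """
    cfg = cfg or ProtocolConfig()
    days = day_ids(series.timestamps)
    if day not in set(eligible_test_days(series.X, series.timestamps, cfg)):
        raise ValueError(f"day {day} is not an eligible test day")
    rows = np.where(days == day)[0]
    first = rows[0]
    train = np.arange(0, first + 1)
    test = rows[1:]
    return train, test


# --------------------------------------------------------------------------
# hierarchical MAE
# --------------------------------------------------------------------------

def _timepoint_errors(preds: np.ndarray, actuals: np.ndarray) -> np.ndarray:
    """Item-mean absolute error at each time point (NaN if nothing observed)."""
    err = np.abs(preds - actuals)
    if err.size == 0:
        return np.array([])
    obs = np.isfinite(err)
    cnt = obs.sum(axis=1)
    sums = np.where(obs, err, 0.0).sum(axis=1)
    return np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)


def mae_hierarchical(preds_by_day: dict, actuals_by_day: dict,
                     train_means_by_day: dict | None = None) -> "SubjectEvaluation":
    """Aggregate errors items -> time points -> days -> subject.

    ``preds_by_day[d]`` and ``actuals_by_day[d]`` are (n_points x n_items)
    arrays for test day d; predictions on the centered scale are first
    de-centered with ``train_means_by_day[d]`` when given. Missing cells
    (NaN in actuals) are skipped.
    """
    per_day = {}
    item_err_sum = None
    item_err_cnt = None
    for d, preds in preds_by_day.items():
        actual = np.asarray(actuals_by_day[d], dtype=float)
        preds = np.asarray(preds, dtype=float)
        if train_means_by_day is not None:
            preds = decenter(preds, train_means_by_day[d])
        tp = _timepoint_errors(preds, actual)
        tp = tp[np.isfinite(tp)]
        if tp.size == 0:
            continue
        per_day[d] = float(np.mean(tp))
        err = np.abs(preds - actual)
        obs = np.isfinite(err)
        if item_err_sum is None:
            item_err_sum = np.zeros(err.shape[1])
            item_err_cnt = np.zeros(err.shape[1])
        item_err_sum += np.where(obs, err, 0.0).sum(axis=0)
        item_err_cnt += obs.sum(axis=0)
    if not per_day:
        raise ValueError("no scored cells: every test point is missing")
    per_item = np.where(item_err_cnt > 0, item_err_sum / np.maximum(item_err_cnt, 1),
                        np.nan)
    return SubjectEvaluation(per_day_mae=per_day,
                             overall_mae=float(np.mean(list(per_day.values()))),
                             intervention_mae=np.nan,
                             per_item_mae=per_item,
                             eligible_days=sorted(per_day))


def mae_post_emi(preds_by_day: dict, actuals_by_day: dict,
                 post_emi_by_day: dict,
                 train_means_by_day: dict | None = None) -> float:
    """Same hierarchy restricted to time points whose predecessor row carried
    any intervention; NaN (flagged undefined) when no such point exists."""
    per_day = []
    for d, preds in preds_by_day.items():
        sel = np.asarray(post_emi_by_day[d], dtype=bool)
        if not sel.any():
            continue
        preds = np.asarray(preds, dtype=float)[sel]
        actual = np.asarray(actuals_by_day[d], dtype=float)[sel]
        if train_means_by_day is not None:
            preds = decenter(preds, train_means_by_day[d])
        tp = _timepoint_errors(preds, actual)
        tp = tp[np.isfinite(tp)]
        if tp.size:
            per_day.append(float(np.mean(tp)))
    return float(np.mean(per_day)) if per_day else float("nan")


# --------------------------------------------------------------------------
# per-subject driver
# --------------------------------------------------------------------------

def evaluate_subject(study: SimulatedStudy, model_factory: Callable[[int], object],
                     cfg: ProtocolConfig | None = None, seed: int = 0,
                     deterministic: bool = False) -> SubjectEvaluation:
    """Run the full rolling-origin protocol for one participant.

    ``model_factory(seed)`` returns an unfitted forecaster; deterministic
    models are fitted once per day, stochastic ones as an ensemble of
    ``cfg.ensemble_size`` members whose mean forecast is scored.
    """
    cfg = cfg or ProtocolConfig()
    X, U, ts = study.ema.values, study.emi.U, study.ema.timestamps
    series = AlignedSeries(X=X, U=U, timestamps=ts)
    days = eligible_test_days(X, ts, cfg)
    if not days:
        raise ValueError("participant has no eligible test day")
    preds_by_day, actuals_by_day, means_by_day, post_by_day = {}, {}, {}, {}
    for d in days:
        train, test = rolling_origin_split(series, d, cfg)
        test = test[:cfg.horizon]
        if test.size == 0:
            continue
        Xtr = causal_smooth(X[train], ts[train], cfg.smoothing)
        Xtr_c, _, means = center_split(Xtr)
        horizon = test.size
        # inputs driving the transitions into the test rows
        input_rows = np.concatenate([[train[-1]], test[:-1]])
        U_future = U[input_rows]
        if deterministic:
            model = model_factory(seed)
            model.fit(Xtr_c, U[train])
            pred_c = model.predict(U_future=U_future, horizon=horizon)
        else:
            members = fit_ensemble(lambda s: model_factory(s), Xtr_c, U[train],
                                   n_members=cfg.ensemble_size,
                                   seed=seed + 97 * d)
            pred_c = ensemble_forecast(members, U_future=U_future, horizon=horizon)
        preds_by_day[d] = pred_c
        actuals_by_day[d] = X[test]
        means_by_day[d] = means
        post_by_day[d] = U[input_rows].sum(axis=1) > 0
    ev = mae_hierarchical(preds_by_day, actuals_by_day, means_by_day)
    ev.intervention_mae = mae_post_emi(preds_by_day, actuals_by_day,
                                       post_by_day, means_by_day)
    return ev


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

def compare_models(mae_by_model: dict, reference: str) -> pd.DataFrame:
    """Paired t-tests of each model against a reference, Bonferroni-corrected.

    ``mae_by_model`` maps model name -> per-subject MAE array (aligned across
    models; NaN marks a failed fit, dropped pairwise so the degrees of freedom
    shrink accordingly).
    """
    if reference not in mae_by_model:
        raise ValueError(f"reference model {reference!r} missing")
    others = [k for k in mae_by_model if k != reference]
    n_comp = len(others)
    ref = np.asarray(mae_by_model[reference], dtype=float)
    rows = []
    for name in others:
        vals = np.asarray(mae_by_model[name], dtype=float)
        ok = np.isfinite(vals) & np.isfinite(ref)
        if ok.sum() < 2:
            raise ValueError(f"fewer than two complete pairs for {name!r}")
        diff = vals[ok] - ref[ok]
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(vals[ok], ref[ok])
        rows.append({"model": name, "n": int(ok.sum()), "dof": int(ok.sum() - 1),
                     "mean_mae": float(np.nanmean(vals[ok])),
                     "t": float(t), "p": float(p),
                     "p_bonf": float(min(p * n_comp, 1.0))})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# data ablation
# --------------------------------------------------------------------------

def _farthest_point_days(days: Sequence[int], k: int) -> list[int]:
    """Greedy maximally spaced subset of k day ids."""
    days = sorted(days)
    if len(days) <= k:
        return days
    chosen = [days[0], days[-1]]
    rest = [d for d in days if d not in chosen]
    while len(chosen) < k and rest:
        best = max(rest, key=lambda d: min(abs(d - c) for c in chosen))
        chosen.append(best)
        rest.remove(best)
    return sorted(chosen)


def run_data_ablation(cohort: list, model_factory: Callable[[int], object],
                      windows: Sequence[int] = (30, 40, 50, 60, 70, 80),
                      compliance_rates: Sequence[float] = (0.8, 0.6, 0.4, 0.2),
                      n_repeats: int = 5, n_test_days: int = 10,
                      min_step: int = 80, seed: int = 0,
                      cfg: ProtocolConfig | None = None) -> pd.DataFrame:
    """Training-window length x compliance grid of forecast MAE.

    Subjects qualify when they have at least ``n_test_days`` eligible test
    days whose first survey falls at or after time step ``min_step``; per
    subject, ``n_test_days`` maximally spaced days are scored. Masking at rate
    r retains each training row with probability r, independently per repeat;
    repeats are averaged.
    """
    cfg = cfg or ProtocolConfig()
    rng = np.random.default_rng(seed)
    rows = []
    qualified = 0
    for study in cohort:
        X, U, ts = study.ema.values, study.emi.U, study.ema.timestamps
        series = AlignedSeries(X=X, U=U, timestamps=ts)
        days = eligible_test_days(X, ts, cfg)
        ids = day_ids(ts)
        d_after = [d for d in days if np.where(ids == d)[0][0] >= min_step]
        if len(d_after) < n_test_days:
            continue
        qualified += 1
        test_days = _farthest_point_days(d_after, n_test_days)
        for d in test_days:
            train, test = rolling_origin_split(series, d, cfg)
            test = test[:cfg.horizon]
            if test.size == 0:
                continue
            for window in windows:
                tr = train[-window:]
                for rate in compliance_rates:
                    for rep in range(n_repeats):
                        keep = rng.random(tr.size) < rate
                        keep[-1] = True  # forecast context must exist
                        Xw = X[tr].copy()
                        Xw[~keep] = np.nan
                        try:
                            Xs = causal_smooth(Xw, ts[tr], cfg.smoothing)
                            Xc, _, means = center_split(Xs)
                            model = model_factory(seed + rep)
                            model.fit(Xc, U[tr])
                            input_rows = np.concatenate([[tr[-1]], test[:-1]])
                            pred = decenter(model.predict(U_future=U[input_rows],
                                                          horizon=test.size),
                                            means)
                            tp = _timepoint_errors(pred, X[test])
                            mae = float(np.nanmean(tp[np.isfinite(tp)]))
                        except (ValueError, np.linalg.LinAlgError):
                            mae = np.nan
                        rows.append({"subject": study.subject_id, "day": d,
                                     "window": window, "rate": rate,
                                     "repeat": rep, "mae": mae})
    if qualified == 0:
        raise ValueError("no subject has enough late eligible test days")
    df = pd.DataFrame(rows)
    return (df.groupby(["subject", "window", "rate"], as_index=False)["mae"]
            .mean())


# --------------------------------------------------------------------------
# stationarity
# --------------------------------------------------------------------------

def stationarity_classify(X: np.ndarray, alpha: float = 0.05,
                          min_points: int = 20) -> pd.DataFrame:
    """Per-item augmented Dickey-Fuller screen at level ``alpha``.

    Returns a frame with columns item, testable, stationary, pvalue. Items
    with fewer than ``min_points`` observations or a (numerically) constant
    series are flagged untestable.
    """
    from statsmodels.tsa.stattools import adfuller

    X = np.asarray(X, dtype=float)
    rows = []
    for i in range(X.shape[1]):
        xi = X[:, i][~np.isnan(X[:, i])]
        if xi.size < min_points or np.ptp(xi) == 0:
            rows.append({"item": i, "testable": False, "stationary": False,
                         "pvalue": np.nan})
            continue
        try:
            p = adfuller(xi, autolag="AIC")[1]
        except Exception:
            rows.append({"item": i, "testable": False, "stationary": False,
                         "pvalue": np.nan})
            continue
        rows.append({"item": i, "testable": True, "stationary": bool(p < alpha),
                     "pvalue": float(p)})
    return pd.DataFrame(rows)
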