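"""Validating predicted intervention effects against proximal outcomes.

Predicted per-type effects (one-step relative cumulative impulse responses)
are compared with empirical proximal effects — the item-mean one-step change
in the observed series right after each delivery — using weighted Spearman
correlations (weights = per-type delivery counts), aggregated across subjects
by Fisher-z transformation. Significance comes from two resampling schemes: a
hierarchical bootstrap over subjects and within-subject type pairs, and a
null-timing bootstrap that shuffles intervention timestamps while preserving
the outcome time courses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EmiEffectTable", "empirical_proximal_effect", "weighted_spearman",
    "fisher_z_aggregate", "hierarchical_bootstrap", "null_timing_bootstrap",
]


@dataclass
class EmiEffectTable:
    """Per subject x intervention type: predicted effect, empirical effect,
    delivery count (the correlation weight)."""

    predicted: np.ndarray       # subjects x types
    empirical: np.ndarray       # subjects x types (NaN = type never delivered)
    counts: np.ndarray          # subjects x types

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.empirical = np.asarray(self.empirical, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if not (self.predicted.shape == self.empirical.shape == self.counts.shape):
            raise ValueError("predicted, empirical, counts must share shape")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def complete_subjects(self) -> np.ndarray:
        """Subjects that received every intervention type at least once."""
        return (self.counts > 0).all(axis=1)


def empirical_proximal_effect(X: np.ndarray, U: np.ndarray):
    """Mean one-step change after each intervention type.

    For every delivery at row t with a following row t+1, the effect is the
    item-mean of (x_{t+1} - x_t) over items observed at both rows (scores on
    the recoded, higher-is-better scale). Deliveries at the final row are
    skipped. Returns (effects, counts); a type never delivered (or never
    scoreable) has effect NaN and count 0.
    """
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    T, m = U.shape
    sums = np.zeros(m)
    counts = np.zeros(m)
    for t in range(T - 1):
        types = np.where(U[t] == 1.0)[0]
        if types.size == 0:
            continue
        both = ~np.isnan(X[t]) & ~np.isnan(X[t + 1])
        if not both.any():
            continue
        change = float(np.mean(X[t + 1, both] - X[t, both]))
        for j in types:
            sums[j] += change
            counts[j] += 1
    effects = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return effects, counts


def weighted_spearman(pred: np.ndarray, emp: np.ndarray,
                      weights: np.ndarray | None = None) -> float:
    """Weighted Pearson correlation of (average-tie) rank vectors.

    With equal weights this reduces to the classical Spearman rho. NaN is
    returned (flagged undefined) when either rank vector has zero weighted
    variance.
    """
    pred = np.asarray(pred, dtype=float)
    emp = np.asarray(emp, dtype=float)
    if weights is None:
        weights = np.ones_like(pred)
    w = np.asarray(weights, dtype=float)
    ok = np.isfinite(pred) & np.isfinite(emp) & (w > 0)
    if ok.sum() < 3:
        raise ValueError("need at least three weighted pairs")
    rp = stats.rankdata(pred[ok], method="average")
    re = stats.rankdata(emp[ok], method="average")
    w = w[ok] / w[ok].sum()
    mp, me = np.sum(w * rp), np.sum(w * re)
    cov = np.sum(w * (rp - mp) * (re - me))
    vp = np.sum(w * (rp - mp) ** 2)
    ve = np.sum(w * (re - me) ** 2)
    if vp == 0 or ve == 0:
        logger.warning("zero-variance ranks; weighted Spearman undefined")
        return float("nan")
    return float(cov / np.sqrt(vp * ve))


def fisher_z_aggregate(correlations) -> tuple[float, float]:
    """Mean and standard error computed in Fisher-z space.

    Correlations at exactly +-1 are clipped to +-(1 - 1e-6) with a warning.
    Returns (mean_rho, se_rho) with the mean back-transformed and the SE
    propagated through the inverse transform at the mean.
    """
    r = np.asarray(list(correlations), dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no finite correlations to aggregate")
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("correlation(s) at |rho| = 1 clipped for Fisher transform")
        r = np.clip(r, -1 + 1e-6, 1 - 1e-6)
    z = np.arctanh(r)
    zm = z.mean()
    se_z = z.std(ddof=1) / np.sqrt(z.size) if z.size > 1 else 0.0
    # delta method: d tanh / dz at the mean
    return float(np.tanh(zm)), float(se_z * (1 - np.tanh(zm) ** 2))


def _subject_rhos(table: EmiEffectTable) -> list[float]:
    rhos = []
    for s in range(table.predicted.shape[0]):
        try:
            rho = weighted_spearman(table.predicted[s], table.empirical[s],
                                    table.counts[s])
        except ValueError:
            continue
        if np.isfinite(rho):
            rhos.append(rho)
    return rhos


def hierarchical_bootstrap(table: EmiEffectTable, B: int = 5000, seed: int = 0,
                           max_redraws: int = 100):
    """Bootstrap the Fisher-z mean weighted correlation.

    Each replicate resamples subjects with replacement and, within each
    drawn subject, intervention-type effect pairs with replacement; subject
    resamples with degenerate (all-tied) ranks are redrawn, with the count
    logged. Returns a dict with the observed mean, percentile CI, one-sided
    p (fraction of bootstrap means <= 0) and the bootstrap distribution.
    """
    if table.predicted.shape[0] < 2:
        raise ValueError("need at least two subjects")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    S, m = table.predicted.shape
    observed, _ = fisher_z_aggregate(_subject_rhos(table))
    boot = np.empty(B)
    n_redraws = 0
    for rep in range(B):
        subj = rng.integers(0, S, size=S)
        rhos = []
        for s in subj:
            ok = np.isfinite(table.predicted[s]) & np.isfinite(table.empirical[s]) \
                & (table.counts[s] > 0)
            idx_pool = np.where(ok)[0]
            if idx_pool.size < 3:
                continue
            rho = np.nan
            for _ in range(max_redraws):
                pick = rng.choice(idx_pool, size=idx_pool.size, replace=True)
                try:
                    rho = weighted_spearman(table.predicted[s][pick],
                                            table.empirical[s][pick],
                                            table.counts[s][pick])
                except ValueError:
                    rho = np.nan
                if np.isfinite(rho):
                    break
                n_redraws += 1
            if np.isfinite(rho):
                rhos.append(rho)
        if rhos:
            boot[rep], _ = fisher_z_aggregate(rhos)
        else:
            boot[rep] = np.nan
    boot = boot[np.isfinite(boot)]
    if n_redraws:
        logger.info("hierarchical bootstrap: %d degenerate resamples redrawn",
                    n_redraws)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    p = float((np.sum(boot <= 0) + 1) / (boot.size + 1))
    return {"mean_rho": observed, "ci": ci, "p": p, "distribution": boot,
            "n_redraws": n_redraws}


def null_timing_bootstrap(X_by_subject: list, U_by_subject: list,
                          predicted_by_subject: list, B: int = 1000,
                          seed: int = 0):
    """Null distribution of the mean weighted correlation under shuffled
    intervention timing.

    Per replicate, each subject's input rows are permuted over the
    observation grid (conserving per-type delivery counts), empirical
    proximal effects are recomputed and correlated with the fixed predicted
    effects. Empirical p = fraction of null means >= the observed mean.
    """
    if B < 100:
        warnings.warn("null-timing bootstrap with B < 100 is unreliable")
    rng = np.random.default_rng(seed)

    def mean_rho(U_list):
        rhos = []
        for X, U, pred in zip(X_by_subject, U_list, predicted_by_subject):
            emp, counts = empirical_proximal_effect(X, U)
            try:
                rho = weighted_spearman(pred, emp, counts)
            except ValueError:
                continue
            if np.isfinite(rho):
                rhos.append(rho)
        if not rhos:
            return np.nan
        return fisher_z_aggregate(rhos)[0]

    observed = mean_rho(U_by_subject)
    null = np.empty(B)
    for rep in range(B):
        permuted = [U[rng.permutation(U.shape[0])] for U in U_by_subject]
        null[rep] = mean_rho(permuted)
    null = null[np.isfinite(null)]
    p = float((np.sum(null >= observed) + 1) / (null.size + 1))
    return {"observed_mean_rho": float(observed), "p": p, "null_distribution": null}
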