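"""Simulated perturbations of fitted dynamics: cumulative impulse responses,
node-targeted input design, selectivity scores and intervention ranking.

The seven-step cumulative impulse response (roughly a 24-hour horizon) of an
input u from an initial observation x0 is

    CIR_7(u, x0) = sum_{t=1..7} ( B f^t(G x0, u) - x0 ),

with f the latent transition, G the recognition map into latent space and B
the observation map. The relative CIR (rCIR) subtracts the no-input
trajectory CIR_7(0, x0), isolating the input-driven component; rCIR_1 is its
one-step analogue. Responses are averaged over representative initial
conditions (the null vector and all standard basis vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import recognition_gain_kalman, recognition_gain_plrnn
from .models import KalmanForecaster, PLRNNForecaster, VAR1Forecaster

__all__ = [
    "PerturbationInput", "CirResult", "latent_interface", "simulate_cir",
    "average_over_initials", "design_node_input", "selectivity_score",
    "total_rcir", "rank_emi_effects", "categorize_emi_effects",
]


@dataclass
class PerturbationInput:
    u: np.ndarray
    label: str = ""
    mode: str = "impulse"        # impulse | sustained

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if not np.all(np.isfinite(self.u)):
            raise ValueError("input vector must be finite")
        if self.mode not in ("impulse", "sustained"):
            raise ValueError("mode must be 'impulse' or 'sustained'")


@dataclass
class CirResult:
    responses: np.ndarray        # steps x n, input-trajectory response B f^t - x0
    rcir_steps: np.ndarray       # steps x n, per-step difference to no-input run
    cir7: np.ndarray             # length n (input trajectory)
    rcir: np.ndarray             # length n, cir7(u) - cir7(0)
    rcir1: np.ndarray            # length n, one-step relative response
    initial_conditions: str = "single"
    mode: str = "impulse"

    @property
    def total_rcir(self) -> float:
        return float(self.rcir.sum())


# --------------------------------------------------------------------------
# model interface
# --------------------------------------------------------------------------

def latent_interface(model):
    """(step, B, G, input_dim) for models with an explicit latent rollout.

    VAR(1) acts in observation space (B = G = I); static baselines and the
    Transformer expose no latent dynamics and are rejected.
    """
    if isinstance(model, PLRNNForecaster):
        G = recognition_gain_plrnn(model.B_, model.Gamma_)
        return model.latent_step, model.B_, G, model.n_inputs_
    if isinstance(model, KalmanForecaster):
        G = recognition_gain_kalman(model.A_, model.B_, model.Q_, model.Gamma_)
        return model.latent_step, model.B_, G, model.n_inputs_
    if isinstance(model, VAR1Forecaster):
        n = model.n_items_

        def step(z, u):
            return model.A_ @ z + model.C_ @ u + model.h_

        return step, np.eye(n), np.eye(n), model.n_inputs_
    raise TypeError(f"{type(model).__name__} has no latent rollout; "
                    "perturbation analysis needs a dynamical model")


def simulate_cir(model, u: np.ndarray, x0: np.ndarray, steps: int = 7,
                 mode: str = "impulse") -> CirResult:
    """Roll the dynamics with and without input u from observation x0.

    In impulse mode u drives only the first transition; in sustained mode it
    is applied at every step.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    step, B, G, m = latent_interface(model)
    u = np.asarray(u, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    zero = np.zeros(m)
    resp_u = np.empty((steps, x0.size))
    resp_0 = np.empty((steps, x0.size))
    z_u = G @ x0
    z_0 = z_u.copy()
    for t in range(steps):
        drive = u if (t == 0 or mode == "sustained") else zero
        z_u = step(z_u, drive)
        z_0 = step(z_0, zero)
        resp_u[t] = B @ z_u - x0
        resp_0[t] = B @ z_0 - x0
    rsteps = resp_u - resp_0
    return CirResult(responses=resp_u, rcir_steps=rsteps,
                     cir7=resp_u.sum(axis=0), rcir=rsteps.sum(axis=0),
                     rcir1=rsteps[0], mode=mode)


def average_over_initials(model, u: np.ndarray, steps: int = 7,
                          mode: str = "impulse") -> CirResult:
    """Mean CIR over the null vector and all standard basis vectors.

    For linear dynamics the initial condition cancels in the relative
    response, so the average equals any single-x0 result.
    """
    _, B, _, _ = latent_interface(model)
    n = B.shape[0]
    inits = [np.zeros(n)] + [np.eye(n)[i] for i in range(n)]
    results = [simulate_cir(model, u, x0, steps=steps, mode=mode) for x0 in inits]
    return CirResult(
        responses=np.mean([r.responses for r in results], axis=0),
        rcir_steps=np.mean([r.rcir_steps for r in results], axis=0),
        cir7=np.mean([r.cir7 for r in results], axis=0),
        rcir=np.mean([r.rcir for r in results], axis=0),
        rcir1=np.mean([r.rcir1 for r in results], axis=0),
        initial_conditions=f"null+{n} basis vectors", mode=mode)


# --------------------------------------------------------------------------
# node targeting and selectivity
# --------------------------------------------------------------------------

def observation_input_map(model) -> np.ndarray:
    """Immediate observation-level effect of a unit input: D = B C."""
    _, B, _, _ = latent_interface(model)
    return B @ model.C_


def design_node_input(model, target: int, tol: float = 1e-10) -> PerturbationInput:
    """Input direction whose immediate effect D u is maximally cosine-aligned
    with the target item's basis vector; closed form u = pinv(D) e_j,
    returned with unit Euclidean norm."""
    D = observation_input_map(model)
    if np.allclose(D, 0.0):
        raise ValueError("input map D = B C is zero; no item is reachable")
    n = D.shape[0]
    e = np.zeros(n)
    e[target] = 1.0
    u = np.linalg.pinv(D) @ e
    if np.linalg.norm(D @ u) < tol:
        raise ValueError(f"item {target} is unreachable: column space of D "
                         "is orthogonal to its basis vector")
    return PerturbationInput(u=u / np.linalg.norm(u), label=f"node:{target}")


def selectivity_score(D: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Normalized absolute effect share per item: s_j = |(Du)_j| / sum_i |(Du)_i|.

    Equals 1 on the target for a perfectly item-specific perturbation and
    1/n when the effect spreads uniformly over the n items.
    """
    v = np.abs(np.asarray(D, dtype=float) @ np.asarray(u, dtype=float))
    tot = v.sum()
    if tot == 0:
        raise ValueError("Du = 0: perturbation has no observation-level effect")
    return v / tot


def total_rcir(result: CirResult) -> float:
    """Signed sum of the relative response across items."""
    return result.total_rcir


def standardize_totals(totals: np.ndarray) -> np.ndarray:
    """Within-subject z-scores of node-input totals (for cross-subject plots)."""
    totals = np.asarray(totals, dtype=float)
    sd = totals.std(ddof=0)
    if sd == 0:
        return np.zeros_like(totals)
    return (totals - totals.mean()) / sd


# --------------------------------------------------------------------------
# intervention ranking
# --------------------------------------------------------------------------

def rank_emi_effects(model, n_types: int | None = None, steps: int = 7,
                     mode: str = "impulse") -> pd.DataFrame:
    """Predicted effectiveness of each intervention type.

    One-hot inputs per type; effectiveness summarized as the item-mean rCIR_1
    and rCIR_7 (averaged over representative initial conditions). Ranks are
    descending (rank 1 = most beneficial); exact ties are broken by type
    index and flagged.
    """
    m = n_types if n_types is not None else model.n_inputs_
    if m < 2:
        raise ValueError("ranking needs at least two intervention types")
    rows = []
    for j in range(m):
        u = np.zeros(m)
        u[j] = 1.0
        res = average_over_initials(model, u, steps=steps, mode=mode)
        rows.append({"emi": j, "rcir1": float(res.rcir1.mean()),
                     "rcir7": float(res.rcir.mean())})
    df = pd.DataFrame(rows)
    for col in ("rcir1", "rcir7"):
        order = np.lexsort((df["emi"].to_numpy(), -df[col].to_numpy()))
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(1, m + 1)
        df[f"rank_{col}"] = ranks
    df["tied"] = df.duplicated("rcir7", keep=False) | df.duplicated("rcir1", keep=False)
    return df


def categorize_emi_effects(per_subject_rcir7: np.ndarray,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Classify each intervention type across subjects.

    ``per_subject_rcir7`` has shape (subjects, types, items). Categories, via
    sign tests on per-item responses with Bonferroni correction over types:
    'significantly positive' (total response > 0), 'selectively positive'
    (some item significantly positive, total not), 'adverse' (total < 0),
    else 'neutral'. The category definitions are a documented convention.
    """
    R = np.asarray(per_subject_rcir7, dtype=float)
    S, m, n = R.shape
    rows = []
    for j in range(m):
        totals = R[:, j, :].sum(axis=1)
        t_tot, p_tot = stats.ttest_1samp(totals, 0.0) if totals.std(ddof=1) > 0 \
            else (0.0, 1.0)
        p_tot = min(float(p_tot) * m, 1.0)
        item_sig_pos = False
        for i in range(n):
            vals = R[:, j, i]
            if vals.std(ddof=1) == 0:
                continue
            t, p = stats.ttest_1samp(vals, 0.0)
            if min(float(p) * m * n, 1.0) < alpha and vals.mean() > 0:
                item_sig_pos = True
        if p_tot < alpha and totals.mean() > 0:
            cat = "significantly positive"
        elif p_tot < alpha and totals.mean() < 0:
            cat = "adverse"
        elif item_sig_pos:
            cat = "selectively positive"
        else:
            cat = "neutral"
        rows.append({"emi": j, "mean_total_rcir7": float(totals.mean()),
                     "p_bonf": p_tot, "category": cat})
    return pd.DataFrame(rows)
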