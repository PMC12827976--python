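"""Synthetic EMA/EMI cohorts with known ground-truth dynamics.

Emulates a 40-day micro-randomized trial: a 10-day training phase with eight
EMA surveys per day during which each of the eight intervention (EMI) types
is delivered exactly twice, followed by a 30-day assessment phase with six
EMA surveys per day, an optional interactive EMI after each survey and one
daily consolidation EMI. Participants' momentary states evolve under a known
latent dynamical system (linear VAR or piecewise-linear RNN) with
item-specific intervention effects, and are observed on 1-7 Likert scales
with partial compliance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "GroundTruthModel",
    "EmaSeries",
    "EmiSequence",
    "SimulatedStudy",
    "generate_schedule",
    "simulate_participant",
    "simulate_cohort",
    "sample_ground_truth",
    "write_study_csv",
    "read_study_csv",
]

# EMA delivery window within each day (hours from midnight); the waking
# interval within which survey prompts are randomized.
DAY_WINDOW = (8.0, 22.0)

DEFAULT_ITEM_NAMES = [
    "mood", "relaxed", "stress", "anxiety", "worry", "energetic", "tired",
    "confidence", "satisfied", "disappointed", "resilience", "focus",
    "motivation", "loneliness", "optimism",
]

# Items phrased negatively (higher raw score = worse); recoded at ingestion.
DEFAULT_REVERSED = ("stress", "anxiety", "worry", "tired", "disappointed", "loneliness")


@dataclass
class StudyDesign:
    """Trial schedule parameters (defaults follow the 40-day design)."""

    n_items: int = 15
    likert_min: int = 1
    likert_max: int = 7
    n_emi_types: int = 8
    training_days: int = 10
    assessment_days: int = 30
    surveys_per_day_training: int = 8
    surveys_per_day_assessment: int = 6
    consolidation_per_day: int = 1
    interactive_accept_prob: float = 0.3
    compliance: float = 0.85

    def __post_init__(self):
        for name in ("n_items", "likert_min", "likert_max", "n_emi_types",
                     "surveys_per_day_training", "surveys_per_day_assessment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("training_days", "assessment_days", "consolidation_per_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("interactive_accept_prob", "compliance"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.likert_min >= self.likert_max:
            raise ValueError("likert_min must be below likert_max")

    @property
    def n_days(self) -> int:
        return self.training_days + self.assessment_days

    @property
    def n_ema_slots(self) -> int:
        return (self.training_days * self.surveys_per_day_training
                + self.assessment_days * self.surveys_per_day_assessment)


@dataclass
class GroundTruthModel:
    """Generative latent dynamics with intervention inputs.

    family='var':    z_t = A z_{t-1} + C u_{t-1} + h + noise
    family='plrnn':  z_t = A z_{t-1} + W1 (relu(W2 z + b) - relu(W2 z)) + C u_{t-1} + h + noise
    Observations: x_t = B z_t + baseline + obs noise, rounded and clipped to
    the Likert range.
    """

    family: str
    latent_dim: int
    A: np.ndarray
    C: np.ndarray
    B: np.ndarray
    h: np.ndarray
    W1: np.ndarray | None = None
    W2: np.ndarray | None = None
    b: np.ndarray | None = None
    baseline: np.ndarray | None = None
    process_noise_sd: float = 0.1
    obs_noise_sd: float = 0.1

    def __post_init__(self):
        if self.family not in ("var", "plrnn"):
            raise ValueError(f"unknown family {self.family!r}")
        self.A = np.asarray(self.A, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        l = self.latent_dim
        if self.A.shape != (l, l):
            raise ValueError("A must be latent_dim x latent_dim")
        if self.C.shape[0] != l or self.B.shape[1] != l or self.h.shape != (l,):
            raise ValueError("C, B, h dimensions inconsistent with latent_dim")
        if self.process_noise_sd < 0 or self.obs_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.family == "var":
            if np.max(np.abs(np.linalg.eigvals(self.A))) >= 1.0:
                raise ValueError("A has spectral radius >= 1 (unstable var truth)")
        else:
            if self.W1 is None or self.W2 is None or self.b is None:
                raise ValueError("plrnn truth requires W1, W2, b")
            self.W1 = np.asarray(self.W1, dtype=float)
            self.W2 = np.asarray(self.W2, dtype=float)
            self.b = np.asarray(self.b, dtype=float)
        if self.baseline is None:
            mid = 4.0
            self.baseline = np.full(self.B.shape[0], mid)
        else:
            self.baseline = np.asarray(self.baseline, dtype=float)

    @property
    def n_items(self) -> int:
        return self.B.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.C.shape[1]

    def step(self, z: np.ndarray, u: np.ndarray) -> np.ndarray:
        """One deterministic latent transition."""
        out = self.A @ z + self.C @ u + self.h
        if self.family == "plrnn":
            pre = self.W2 @ z
            out = out + self.W1 @ (np.maximum(pre + self.b, 0) - np.maximum(pre, 0))
        return out


@dataclass
class EmaSeries:
    """Observed EMA matrix (NaN = missing) with continuous-hour timestamps."""

    values: np.ndarray          # T x n, NaN for missing cells
    timestamps: np.ndarray      # T hours since study start
    item_names: list[str] = field(default_factory=list)
    reversed_items: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValueError("values and timestamps disagree on T")
        if not self.item_names:
            self.item_names = [f"item_{i}" for i in range(self.values.shape[1])]

    @property
    def mask(self) -> np.ndarray:
        """True where observed."""
        return ~np.isnan(self.values)

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


@dataclass
class EmiSequence:
    """Binary intervention-input matrix aligned row-wise with an EmaSeries."""

    U: np.ndarray               # T x m, entries in {0, 1}
    emi_names: list[str] = field(default_factory=list)
    covariates: np.ndarray | None = None   # optional T x k extra channels

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        if not np.isin(self.U, (0.0, 1.0)).all():
            raise ValueError("U entries must be binary")
        if not self.emi_names:
            self.emi_names = [f"emi_{i}" for i in range(self.U.shape[1])]

    @property
    def n_types(self) -> int:
        return self.U.shape[1]

    def with_covariates(self) -> np.ndarray:
        if self.covariates is None:
            return self.U
        return np.concatenate([self.U, self.covariates], axis=1)


@dataclass
class SimulatedStudy:
    ema: EmaSeries
    emi: EmiSequence
    truth: GroundTruthModel | None
    seed: int
    subject_id: str = "s0"

    def __post_init__(self):
        if self.ema.values.shape[0] != self.emi.U.shape[0]:
            raise ValueError("EMA and EMI matrices must have equal row counts")


# --------------------------------------------------------------------------
# schedule generation
# --------------------------------------------------------------------------

def generate_schedule(design: StudyDesign, seed: int) -> pd.DataFrame:
    """Draw a randomized survey/intervention timetable.

    Returns a time-sorted event table with columns ``timestamp_hours``,
    ``day``, ``kind`` ('ema' | 'emi') and ``emi_type`` (-1 for EMA rows).
    Training-phase EMIs are delivered immediately after randomly chosen EMA
    prompts such that every type occurs exactly twice; assessment-phase EMAs
    each open an interactive EMI opportunity, and one consolidation EMI per
    day arrives at a random time.
    """
    if design.n_days == 0:
        raise ValueError("study must span at least one day")
    rng = np.random.default_rng(seed)
    rows = []
    lo, hi = DAY_WINDOW

    ema_times_by_day = []
    for day in range(design.n_days):
        n_ema = (design.surveys_per_day_training if day < design.training_days
                 else design.surveys_per_day_assessment)
        times = np.sort(rng.uniform(day * 24 + lo, day * 24 + hi, size=n_ema))
        ema_times_by_day.append(times)
        for t in times:
            rows.append((t, day, "ema", -1))

    # training phase: each EMI type exactly twice, right after a random EMA
    train_slots = [t for day in range(design.training_days)
                   for t in ema_times_by_day[day]]
    if design.training_days > 0:
        deliveries = np.repeat(np.arange(design.n_emi_types), 2)
        slot_idx = rng.choice(len(train_slots), size=deliveries.size,
                              replace=len(train_slots) < deliveries.size)
        for emi_type, si in zip(deliveries, slot_idx):
            rows.append((train_slots[si] + 1e-3, int(train_slots[si] // 24),
                         "emi", int(emi_type)))

    # assessment phase: interactive opportunities + daily consolidation
    for day in range(design.training_days, design.n_days):
        for t in ema_times_by_day[day]:
            if rng.random() < design.interactive_accept_prob:
                rows.append((t + 1e-3, day, "emi",
                             int(rng.integers(design.n_emi_types))))
        for _ in range(design.consolidation_per_day):
            tc = rng.uniform(day * 24 + lo, day * 24 + hi)
            rows.append((tc, day, "emi", int(rng.integers(design.n_emi_types))))

    sched = pd.DataFrame(rows, columns=["timestamp_hours", "day", "kind", "emi_type"])
    sched = sched.sort_values("timestamp_hours", kind="mergesort").reset_index(drop=True)
    return sched


# --------------------------------------------------------------------------
# participant simulation
# --------------------------------------------------------------------------

def _assign_emis_to_rows(sched: pd.DataFrame, n_types: int) -> tuple[np.ndarray, np.ndarray]:
    """Map each EMI event to the most recent preceding EMA row; returns (ema_times, U)."""
    ema_times = sched.loc[sched["kind"] == "ema", "timestamp_hours"].to_numpy()
    U = np.zeros((ema_times.size, n_types))
    emi = sched[sched["kind"] == "emi"]
    for t, typ in zip(emi["timestamp_hours"], emi["emi_type"]):
        row = np.searchsorted(ema_times, t, side="right") - 1
        if row >= 0:
            U[row, int(typ)] = 1.0
    return ema_times, U


def simulate_participant(truth: GroundTruthModel, sched: pd.DataFrame,
                         design: StudyDesign, seed: int,
                         divergence_bound: float = 1e6) -> SimulatedStudy:
    """Roll the ground-truth dynamics over a timetable and observe with noise.

    The latent state advances once per EMA slot; the input applied on the
    transition into row ``t`` is the EMI vector attached to row ``t-1``,
    matching the alignment convention the forecasting models assume.
    """
    if truth.n_items != design.n_items:
        raise ValueError("truth observation dimension does not match design.n_items")
    rng = np.random.default_rng(seed)
    ema_times, U = _assign_emis_to_rows(sched, truth.n_inputs)
    T = ema_times.size
    l, n = truth.latent_dim, truth.n_items

    Z = np.zeros((T, l))
    z = truth.h.copy()  # start near the unforced fixed point neighbourhood
    for t in range(T):
        u_prev = U[t - 1] if t > 0 else np.zeros(truth.n_inputs)
        z = truth.step(z, u_prev) + rng.normal(0, truth.process_noise_sd, size=l)
        if not np.all(np.isfinite(z)) or np.max(np.abs(z)) > divergence_bound:
            raise ValueError(
                "ground-truth trajectory diverged (|z| exceeded bound); "
                "offending parameter: transition matrix A (spectral radius "
                f"{np.max(np.abs(np.linalg.eigvals(truth.A))):.3f})")
        Z[t] = z

    Y = Z @ truth.B.T + truth.baseline + rng.normal(0, truth.obs_noise_sd, size=(T, n))
    X = np.clip(np.round(Y), design.likert_min, design.likert_max).astype(float)

    answered = rng.random(T) < design.compliance
    X[~answered] = np.nan

    item_names = (DEFAULT_ITEM_NAMES[:n] if n <= len(DEFAULT_ITEM_NAMES)
                  else [f"item_{i}" for i in range(n)])
    ema = EmaSeries(values=X, timestamps=ema_times, item_names=item_names)
    emi = EmiSequence(U=U)
    return SimulatedStudy(ema=ema, emi=emi, truth=truth, seed=seed)


def simulate_cohort(n_subjects: int, design: StudyDesign,
                    truth_sampler: Callable[[np.random.Generator], GroundTruthModel],
                    seed: int) -> list[SimulatedStudy]:
    """Simulate independent participants with heterogeneous ground truths."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    studies = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        truth = truth_sampler(rng)
        sched = generate_schedule(design, seed=sub_seed)
        study = simulate_participant(truth, sched, design, seed=sub_seed + 1)
        study.subject_id = f"s{i}"
        studies.append(study)
    return studies


def sample_ground_truth(rng: np.random.Generator, design: StudyDesign,
                        family: str = "plrnn", latent_dim: int | None = None,
                        hidden_dim: int = 16, emi_effect_scale: float = 0.8,
                        spectral_radius: float = 0.8,
                        process_noise_sd: float = 0.15,
                        obs_noise_sd: float = 0.2,
                        zero_emi_effect: bool = False) -> GroundTruthModel:
    """Draw a random stable ground truth with sparse, signed EMI effects.

    Each intervention type loads on 2-4 items with signed weights, creating
    recoverable type-specific proximal effects. ``zero_emi_effect`` yields the
    null fixture in which interventions do nothing.
    """
    n, m = design.n_items, design.n_emi_types
    if family == "var":
        l = n
        A = rng.normal(0, 1, size=(l, l))
        A *= spectral_radius / np.max(np.abs(np.linalg.eigvals(A)))
        B = np.eye(n)
        W1 = W2 = b = None
    elif family == "plrnn":
        l = latent_dim if latent_dim is not None else n
        A = np.diag(rng.uniform(0.3, spectral_radius, size=l))
        W1 = rng.normal(0, 0.35 / np.sqrt(hidden_dim), size=(l, hidden_dim))
        W2 = rng.normal(0, 0.35 / np.sqrt(l), size=(hidden_dim, l))
        b = rng.normal(0, 0.5, size=hidden_dim)
        B = rng.normal(0, 1.0 / np.sqrt(l), size=(n, l)) if l != n else np.eye(n)
    else:
        raise ValueError(f"unknown family {family!r}")

    C = np.zeros((l, m))
    if not zero_emi_effect:
        for j in range(m):
            k = rng.integers(2, 5)
            idx = rng.choice(l, size=min(k, l), replace=False)
            C[idx, j] = rng.choice([-1.0, 1.0], size=idx.size) * \
                rng.uniform(0.5, 1.0, size=idx.size) * emi_effect_scale
    h = rng.normal(0, 0.3, size=l)
    baseline = np.clip(rng.normal(4.0, 0.5, size=n), 2.5, 5.5)
    return GroundTruthModel(family=family, latent_dim=l, A=A, C=C, B=B, h=h,
                            W1=W1, W2=W2, b=b, baseline=baseline,
                            process_noise_sd=process_noise_sd,
                            obs_noise_sd=obs_noise_sd)


def simulate_continuous(truth: GroundTruthModel, T: int, seed: int,
                        input_prob: float = 0.0):
    """Plain (un-discretized, fully observed) rollout of the ground truth.

    Useful for parameter-recovery oracles where Likert rounding and
    missingness would confound the comparison. Inputs are i.i.d. Bernoulli
    per type with probability ``input_prob``. Returns (X, U) with
    X centered on the latent observation scale (no baseline shift).
    """
    rng = np.random.default_rng(seed)
    l, n, m = truth.latent_dim, truth.n_items, truth.n_inputs
    U = (rng.random((T, m)) < input_prob).astype(float)
    X = np.empty((T, n))
    z = truth.h.copy()
    for t in range(T):
        u_prev = U[t - 1] if t > 0 else np.zeros(m)
        z = truth.step(z, u_prev) + rng.normal(0, truth.process_noise_sd, size=l)
        X[t] = truth.B @ z + rng.normal(0, truth.obs_noise_sd, size=n)
    return X, U


# --------------------------------------------------------------------------
# long-format CSV I/O
# --------------------------------------------------------------------------

def study_to_events(study: SimulatedStudy) -> pd.DataFrame:
    """Flatten a study into the long event-table dialect."""
    rows = []
    X, ts = study.ema.values, study.ema.timestamps
    for t in range(X.shape[0]):
        for i in range(X.shape[1]):
            if not np.isnan(X[t, i]):
                rows.append((study.subject_id, ts[t], "ema", study.ema.item_names[i],
                             X[t, i]))
        for j in range(study.emi.n_types):
            if study.emi.U[t, j] == 1.0:
                rows.append((study.subject_id, ts[t] + 1e-3, "emi",
                             study.emi.emi_names[j], 1.0))
    return pd.DataFrame(rows, columns=["subject_id", "timestamp_hours",
                                       "event_type", "item_or_emi_id", "value"])


def write_study_csv(study: SimulatedStudy, csv_path, design: StudyDesign | None = None):
    """Write the long event table plus a JSON sidecar with design/truth/seed."""
    events = study_to_events(study)
    events.to_csv(csv_path, index=False)
    sidecar = {"seed": study.seed, "subject_id": study.subject_id}
    if design is not None:
        sidecar["design"] = asdict(design)
    if study.truth is not None:
        td = {}
        for k, v in asdict(study.truth).items():
            td[k] = v.tolist() if isinstance(v, np.ndarray) else v
        sidecar["truth"] = td
    with open(str(csv_path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_study_csv(csv_path, item_names: Sequence[str] | None = None,
                   emi_names: Sequence[str] | None = None) -> SimulatedStudy:
    """Rebuild a SimulatedStudy from the long event table (truth optional)."""
    from .preprocess import build_matrices  # local import avoids a cycle

    events = pd.read_csv(csv_path)
    aligned, meta = build_matrices(events, item_names=item_names,
                                   emi_names=emi_names, recode_reversed=False)
    ema = EmaSeries(values=aligned.X, timestamps=aligned.timestamps,
                    item_names=list(meta["item_names"]))
    emi = EmiSequence(U=aligned.U, emi_names=list(meta["emi_names"]))
    truth = None
    seed = 0
    try:
        with open(str(csv_path) + ".json") as fh:
            sidecar = json.load(fh)
        seed = sidecar.get("seed", 0)
        if "truth" in sidecar:
            td = sidecar["truth"]
            truth = GroundTruthModel(
                family=td["family"], latent_dim=td["latent_dim"],
                A=np.array(td["A"]), C=np.array(td["C"]), B=np.array(td["B"]),
                h=np.array(td["h"]),
                W1=np.array(td["W1"]) if td.get("W1") is not None else None,
                W2=np.array(td["W2"]) if td.get("W2") is not None else None,
                b=np.array(td["b"]) if td.get("b") is not None else None,
                baseline=np.array(td["baseline"]),
                process_noise_sd=td["process_noise_sd"],
                obs_noise_sd=td["obs_noise_sd"])
    except FileNotFoundError:
        pass
    sid = events["subject_id"].iloc[0] if len(events) else "s0"
    return SimulatedStudy(ema=ema, emi=emi, truth=truth, seed=seed, subject_id=sid)
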