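# Methods

This document describes what `emadyn` computes, in the order the pipeline
runs: data generation, preprocessing, the forecasting-model ladder, forecast
evaluation, effective connectivity, perturbation analysis and validation.
Notation: `x_t ∈ R^n` the observed item vector (n = 15 items by default,
1-7 Likert), `u_t ∈ {0,1}^m` the intervention-input vector (m = 8 types),
`z_t ∈ R^l` a latent state. Throughout, the input row attached to
observation `t` drives the transition into `t+1`.

## 1. Synthetic study generation (`emadyn.synthetic`)

The default `StudyDesign` emulates a 40-day micro-randomized trial:

- 10 training days with 8 EMA surveys/day, during which each of the 8 EMI
  types is delivered exactly twice, immediately after randomly chosen
  surveys;
- 30 assessment days with 6 EMA surveys/day, an interactive EMI opportunity
  after each survey (accepted independently with probability 0.3) and one
  consolidation EMI per day at a random time;
- survey times drawn uniformly within the waking window 08:00-22:00;
- 260 scheduled EMA observations in total; row-level compliance 0.85.

Ground truths are either stable VAR(1) systems or shallow PLRNNs (see §3)
with sparse, signed intervention maps `C` (each type loads on 2-4 latent
dimensions). Observations are `B z + baseline + noise`, rounded and clipped
to the Likert range; non-answered surveys are missing rows. A
`zero_emi_effect` flag produces null cohorts (C = 0) for calibration
studies. `simulate_continuous` provides un-discretized, fully observed
rollouts for parameter-recovery oracles.

EMI deliveries are encoded in a binary matrix `U` row-aligned with the EMA
matrix `X`: an intervention is assigned to the most recent preceding EMA
row; interventions before the first EMA are dropped with a logged warning.

## 2. Preprocessing (`emadyn.preprocess`)

- **Causal smoothing** (training data only): the smoothed value at time `t`
  is the weighted mean of observed values at times `s ∈ (t − 4 h, t]` with
  weights `exp(−(t−s)²/(2·1.5²))`, renormalized over included points.
  Missing cells remain missing; isolated points are unchanged.
- **Centering**: per-item training means are subtracted from train and test;
  test data are never smoothed. This keeps a strict train/test information
  barrier and makes forecasts back-transformable to the 1-7 scale.
- Reverse-scored items are recoded to `min + max − value` at ingestion so
  higher always means better.

## 3. The model ladder (`emadyn.models`)

**Static baselines.** Persistence (repeat the last observed value per item),
global mean, and an input-only regression `x_t = C u_{t-1} + h` fitted by
least squares per item.

**VAR(1).** `x_t = A x_{t-1} + C u_{t-1} + h + ε`, fitted by ridge
regression on fully observed consecutive transitions with the penalty on the
`A` block only. If the fitted `A` is unstable, the penalty grows
geometrically until the spectral radius drops below 1 (explicit shrinkage as
a last resort), so forecasts cannot diverge.

**Linear state-space model (Kalman/EM).**
`z_t = A z_{t-1} + C u_{t-1} + h + w_t`, `x_t = B z_t + v_t` with
`w ~ N(0, Q)` and diagonal observation covariance `Γ`. The E-step is the
Kalman filter/RTS smoother with exact per-row missing-cell reduction (only
observed components enter each update); the M-step uses closed-form updates,
with `Q` eigenvalue-floored and `A` rescaled to spectral radius
`≤ 1 − margin` when needed. Several random initializations are run and the
best log-likelihood kept; non-convergence is flagged, not hidden. The EM
log-likelihood is monotone nondecreasing (tested).

**Shallow PLRNN with generalized teacher forcing (GTF).** Latent dynamics

    z_t = A z_{t-1} + W1 (φ(W2 z_{t-1} + b) − φ(W2 z_{t-1})) + h + C u_{t-1}

with `φ = ReLU` and `A` diagonal by default. Training is backpropagation
through time on randomly sampled subsequences; the state carried forward is
the convex combination `α·(data-inferred state) + (1−α)·(model state)` with
`α = 0.1`, where the data-inferred state is `pinv(B) x_t` (treated as a
constant). The loss is the masked squared error of the model-predicted
observations (pre-mixing), so missing cells contribute nothing. A final
teacher-forced pass yields the residual observation covariance `Γ` and the
latent state at the end of training.

**Transformer.** A small encoder-decoder model: the encoder stream carries
the intervention inputs, the decoder stream the observation history, both
with sinusoidal positional encoding; decoder position `t` attends causally
to observations up to `t` and cross-attends causally to input rows up to `t`
(which are known when forecasting `t+1`) and predicts observation `t+1`.
Forecasts are autoregressive over a sliding context window.

The PLRNN and Transformer are trained with Adam on a numpy reverse-mode
autodiff core (`emadyn._autograd`) whose gradients are verified against
central finite differences in the test suite. This replaces an external
deep-learning dependency unavailable in the target environment.

**Ensembles.** Stochastic models are fitted as ensembles of independently
seeded members whose mean forecast is scored; member seeds derive
deterministically from a master seed, so every result is reproducible.

## 4. Forecast evaluation (`emadyn.evaluation`)

**Rolling origin.** For each eligible test day (day ≥ 11, at least 3
completed surveys, completed first survey), the training set is everything
up to and including the day's first survey — known at forecast time and used
as rollout context — and the test set is the day's remaining surveys (up to
a 7-step horizon). Training data are smoothed and centered per split; test
data only centered.

**Hierarchical MAE.** Absolute errors on the 1-7 scale are averaged items →
time points → days → subject, so days with unequal numbers of surveys weigh
equally. A post-intervention MAE restricts to time points whose predecessor
row carried any intervention (NaN-flagged when no such point exists).

**Model comparison.** Paired t-tests of per-subject MAEs against a reference
model with Bonferroni correction; failed fits are NaN and dropped pairwise.

**Ablations and screens.** A training-window × compliance grid (random
row-masking, repeated and averaged) quantifies data requirements; an
augmented Dickey-Fuller screen classifies items as stationary/nonstationary
with explicit untestable flags.

## 5. Effective connectivity (`emadyn.connectivity`)

Connectivity is the Jacobian of the one-step conditional expectation
`E[x_t | x_{t-1} = x]`; entry `(j, i)` is the influence of item `i` on item
`j`.

- VAR: `W = A`.
- Kalman: `W = B A G_KF` with the stationary recognition gain
  `G_KF = Σ_zx Σ_xx^{-1}`, where `Σ_zz` solves the discrete Lyapunov
  equation `Σ = A Σ Aᵀ + Q` (via `scipy.linalg.solve_discrete_lyapunov`).
  Scalar check: a = 0.5, b = 1, q = 0.75, γ = 0 gives W = 0.5.
- PLRNN: `W = B J(z) G_RNN` with the local Jacobian
  `J = A + W1 diag(1[W2 z + b > 0] − 1[W2 z > 0]) W2` of the active linear
  region (open half-space convention at boundaries) and the generalized
  least-squares gain `G_RNN = (Bᵀ Γ^{-1} B)^{-1} Bᵀ Γ^{-1}`.

State-dependent (PLRNN) matrices are averaged along the observed trajectory
and across ensemble members. Group edges are tested with one-sample t-tests
(Bonferroni factor n²). Node centrality is the weighted out-degree: column
sums of |W| excluding self-loops. The maximal Lyapunov exponent of the
autonomous latent dynamics is estimated by the QR method (accumulating
`log R₁₁` of successively re-orthonormalized Jacobian products after
discarding transients); `A = 0.5·I` gives exactly `ln 0.5`.

## 6. Perturbation analysis (`emadyn.perturbation`)

The 7-step cumulative impulse response of input `u` from observation `x₀` is

    CIR₇(u, x₀) = Σ_{t=1..7} ( B f^t(G x₀, u) − x₀ ),

with `f` the latent transition and `G` the recognition map; the relative CIR
(rCIR) subtracts the no-input trajectory, isolating the input-driven
component (`rCIR₁` is the one-step analogue). In impulse mode `u` drives
only the first transition; in sustained mode every transition. Responses are
averaged over representative initial conditions (null vector + all standard
basis vectors); for linear dynamics the initial condition cancels exactly in
the relative response.

**Node targeting.** The immediate observation-level effect of a unit input
is `D = B C`. The input maximally cosine-aligned with item `j`'s basis
vector is `u = pinv(D) e_j` (returned unit-norm); unreachable items raise an
error. **Selectivity** of a perturbation is
`s_j = |(Du)_j| / Σ_i |(Du)_i|`: 1 for a perfectly item-specific effect,
1/n for a uniform one (1/15 ≈ 0.067 at the default design).

**Intervention ranking.** One-hot inputs per EMI type are scored by the
item-mean rCIR₁ and rCIR₇; ranks are descending with deterministic,
flagged tie-breaking. Across subjects, types are categorized
(significantly positive / selectively positive / adverse / neutral) via
t-tests with Bonferroni correction — a documented convention, not a claim of
optimal inference.

## 7. Validation (`emadyn.validation`)

Predicted per-type effects are compared against **empirical proximal
effects**: for each delivery at row `t`, the item-mean one-step change
`mean(x_{t+1} − x_t)` over items observed at both rows, averaged per type.
Agreement per subject is the **weighted Spearman correlation** (weighted
Pearson of average-tie rank vectors, weights = per-type delivery counts);
subject correlations are aggregated by Fisher-z transformation.

Two resampling schemes give significance:

- **Hierarchical bootstrap**: resample subjects with replacement, and
  within each drawn subject resample type pairs with replacement; degenerate
  resamples are redrawn with a logged count. One-sided p = fraction of
  bootstrap means ≤ 0 (add-one corrected), plus a percentile CI.
- **Null-timing bootstrap**: permute each subject's input rows over the
  observation grid (conserving per-type delivery counts), recompute
  empirical effects, and compare the observed mean correlation to the null
  distribution. Under zero-effect simulations the resulting p-values are
  approximately uniform (tested by KS over 100 replicates).

## 8. Numerical conventions and limitations

- All randomness flows from explicit seeds through `numpy` generators;
  ensemble and cohort seeds derive from `SeedSequence.spawn`.
- Stability projections (ridge growth for VAR, spectral rescaling in EM) are
  deliberate bias-for-stability trades, logged in fitted attributes
  (`ridge_`, `converged_`).
- Matrix solves prefer `np.linalg.solve`; singular systems fall back to
  pseudo-inverses or jitter with logged warnings.
- Undefined quantities (no post-intervention test point, zero-variance
  ranks) are NaN-flagged, never silently imputed.
- Problem sizes in tests and the acceptance suite (compressed designs,
  reduced ensembles/epochs, desk-scale cohorts) are runtime-driven choices;
  the defaults in `StudyDesign`, `ProtocolConfig` and the model classes
  reflect the full design. Headline numbers from real-cohort studies are
  not reproducible from synthetic desk-scale data; the acceptance suite
  instead pins the method's analytic constants and directional properties.
- Circadian structure, weekday effects and response-time behavior are out
  of scope; survey timestamps only enter through the smoothing kernel and
  day boundaries.
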