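# emadyn

Forecasting and control-oriented analysis of momentary psychological states
from EMA/EMI time series.

`emadyn` simulates micro-randomized-trial cohorts (ecological momentary
assessments with randomized momentary interventions) whose latent dynamics are
known, fits a ladder of forecasting models to the resulting irregular,
partially missing Likert time series, and then treats the fitted dynamics as
objects of analysis: it extracts item-level effective-connectivity networks,
simulates targeted perturbations (cumulative impulse responses), ranks
intervention types by predicted benefit, and validates those predictions
against empirical proximal effects with weighted-correlation bootstrap
statistics.

## The model ladder

| Model | Class | Dynamics |
|---|---|---|
| Persistence / mean / input regression | `StaticBaseline` | none |
| Vector autoregression | `VAR1Forecaster` | x_t = A x_{t-1} + C u_{t-1} + h |
| Linear state space (Kalman, EM) | `KalmanForecaster` | z_t = A z_{t-1} + C u_{t-1} + h; x = B z |
| Shallow piecewise-linear RNN (GTF) | `PLRNNForecaster` | z_t = A z_{t-1} + W1(φ(W2 z + b) − φ(W2 z)) + C u_{t-1} + h |
| Encoder-decoder Transformer | `TransformerForecaster` | autoregressive attention |

All estimators follow the scikit-learn convention: hyperparameters in
`__init__`, `fit(X, U)` on centered matrices with NaN for missing cells,
fitted arrays with trailing underscores, `predict(U_future, horizon)` rolling
the model forward from the end of training.

## Worked example

```python
import numpy as np
from emadyn import StudyDesign, generate_schedule, sample_ground_truth, simulate_participant
from emadyn.preprocess import causal_smooth, center_split, SmoothingConfig
from emadyn.models import VAR1Forecaster
from emadyn.evaluation import ProtocolConfig, evaluate_subject
from emadyn.connectivity import connectivity, weighted_out_degree
from emadyn.perturbation import rank_emi_effects

design = StudyDesign()                      # 40 days, 260 EMA slots, 8 EMI types
rng = np.random.default_rng(7)
truth = sample_ground_truth(rng, design, family="plrnn", latent_dim=8)
sched = generate_schedule(design, seed=7)
study = simulate_participant(truth, sched, design, seed=8)
# study.ema.values: (260, 15) with NaN; study.emi.U: (260, 8) binary

# rolling-origin forecast evaluation (nightly retraining, 7-step horizon)
ev = evaluate_subject(study, lambda s: VAR1Forecaster(), ProtocolConfig(),
                      deterministic=True)
print(ev.overall_mae, ev.intervention_mae)   # 0.339  0.381 (1-7 Likert scale)

# network + perturbation analysis on the full-series fit
Xs = causal_smooth(study.ema.values, study.ema.timestamps, SmoothingConfig())
Xc, _, _ = center_split(Xs)
model = VAR1Forecaster().fit(Xc, study.emi.U)
deg = weighted_out_degree(connectivity(model)).out_degree
print(rank_emi_effects(model).sort_values("rank_rcir7").head(3))
```

Running the example prints an overall forecast MAE of 0.339 on the 1-7 scale
over 23 eligible test days, and for this subject ranks intervention types 2
and 3 as most beneficial (mean 7-step relative cumulative impulse responses
0.126 and 0.126).

## Command line

```bash
emadyn show-config              # print the default experiment configuration
emadyn run --seed 0 --outdir results          # full pipeline
emadyn run --stage evaluate --outdir results  # a single stage
emadyn report --outdir results                # summary.json + report.md
```

The pipeline writes per-stage artifacts (simulated data CSVs, forecast MAE
tables, model comparisons, connectivity matrices, centrality, node
perturbations, EMI rankings, bootstrap validation summaries), each stamped
with a configuration hash and the master seed.

## Acceptance targets

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

writes the analytic acceptance target (`t1`: the selectivity score of a
perfectly non-selective perturbation over 15 items, 1/15 ≈ 0.067). The full
criterion suite lives in `tests/test_acceptance.py`:

```bash
python -m pytest tests/ -q
```

## Documentation

See `docs/methods.md` for the mathematical account of every stage:
preprocessing, the model equations and training procedures, the
rolling-origin protocol and hierarchical MAE, connectivity/recognition gains,
Lyapunov exponents, cumulative impulse responses and the bootstrap validation
schemes, together with the package's numerical conventions and limitations.
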