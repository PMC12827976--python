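"""Rolling-origin protocol, hierarchical MAE and group statistics."""

import numpy as np
import pandas as pd
import pytest

from emadyn.evaluation import (ProtocolConfig, compare_models, day_ids,
                               eligible_test_days, evaluate_subject,
                               mae_hierarchical, mae_post_emi,
                               rolling_origin_split, run_data_ablation,
                               stationarity_classify)
from emadyn.models import VAR1Forecaster
from emadyn.preprocess import AlignedSeries
from emadyn.synthetic import (generate_schedule, sample_ground_truth,
                              simulate_participant)


def test_day_ids_are_one_based():
    assert day_ids(np.array([0.5, 23.9, 24.0, 50.0])).tolist() == [1, 1, 2, 3]


def test_eligible_days_respect_phase_and_completeness():
    # 12 days, 4 surveys per day
    ts = np.concatenate([d * 24 + np.array([9.0, 12.0, 15.0, 18.0])
                         for d in range(12)])
    X = np.ones((ts.size, 2))
    cfg = ProtocolConfig(first_eligible_day=11, min_ema_per_day=3)
    assert eligible_test_days(X, ts, cfg) == [11, 12]
    # knock out day 11's first survey
    X2 = X.copy(); X2[40] = np.nan
    assert eligible_test_days(X2, ts, cfg) == [12]
    # without the first-survey requirement it comes back
    cfg2 = ProtocolConfig(first_eligible_day=11, min_ema_per_day=3,
                          require_first_ema=False)
    assert eligible_test_days(X2, ts, cfg2) == [11, 12]
    # too few completed surveys on day 12
    X3 = X.copy(); X3[45:48] = np.nan
    assert eligible_test_days(X3, ts, cfg) == [11]


def test_rolling_origin_split_covers_without_overlap():
    ts = np.concatenate([d * 24 + np.array([9.0, 12.0, 15.0, 18.0])
                         for d in range(12)])
    X = np.ones((ts.size, 2))
    series = AlignedSeries(X=X, U=np.zeros((ts.size, 1)), timestamps=ts)
    cfg = ProtocolConfig(first_eligible_day=11)
    train, test = rolling_origin_split(series, 11, cfg)
    # the day's first survey (row 40) belongs to train as forecast context
    assert train[-1] == 40
    assert test.tolist() == [41, 42, 43]
    assert set(train) & set(test) == set()
    assert sorted(np.concatenate([train, test])) == list(range(44))
    with pytest.raises(ValueError, match="eligible"):
        rolling_origin_split(series, 5, cfg)


def test_mae_hierarchical_hand_computed():
    # day 1: two points with item errors (1, 3) -> 2 and (0, 2) -> 1; day MAE 1.5
    # day 2: one point with errors (2, 2) -> 2; subject MAE (1.5 + 2)/2 = 1.75
    preds = {1: np.array([[4.0, 4.0], [4.0, 4.0]]), 2: np.array([[4.0, 4.0]])}
    acts = {1: np.array([[5.0, 7.0], [4.0, 6.0]]), 2: np.array([[2.0, 6.0]])}
    ev = mae_hierarchical(preds, acts)
    assert ev.per_day_mae == {1: 1.5, 2: 2.0}
    assert ev.overall_mae == pytest.approx(1.75)
    assert ev.eligible_days == [1, 2]


def test_mae_hierarchical_skips_missing_cells_and_decenters():
    preds = {1: np.array([[0.0, 0.0]])}
    acts = {1: np.array([[5.0, np.nan]])}
    means = {1: np.array([4.0, 4.0])}
    ev = mae_hierarchical(preds, acts, means)
    assert ev.overall_mae == pytest.approx(1.0)  # |4 - 5|
    assert np.isnan(ev.per_item_mae[1])


def test_mae_hierarchical_raises_when_everything_missing():
    with pytest.raises(ValueError, match="no scored cells"):
        mae_hierarchical({1: np.zeros((1, 2))},
                         {1: np.full((1, 2), np.nan)})


def test_mae_post_emi_subset_and_nan_flag():
    preds = {1: np.array([[4.0], [4.0]])}
    acts = {1: np.array([[6.0], [5.0]])}
    post = {1: np.array([True, False])}
    assert mae_post_emi(preds, acts, post) == pytest.approx(2.0)
    none = {1: np.array([False, False])}
    assert np.isnan(mae_post_emi(preds, acts, none))


def test_evaluate_subject_var_on_short_study(short_design):
    rng = np.random.default_rng(0)
    truth = sample_ground_truth(rng, short_design, family="var")
    sched = generate_schedule(short_design, seed=1)
    study = simulate_participant(truth, sched, short_design, seed=2)
    cfg = ProtocolConfig(first_eligible_day=5, min_ema_per_day=3)
    ev = evaluate_subject(study, lambda s: VAR1Forecaster(), cfg,
                          deterministic=True)
    assert np.isfinite(ev.overall_mae)
    assert 0 < ev.overall_mae < 6.0  # bounded by the Likert range
    assert len(ev.eligible_days) >= 1
    assert ev.per_item_mae.shape == (short_design.n_items,)


def test_compare_models_paired_t_and_bonferroni():
    ref = np.array([1.0, 1.1, 0.9, 1.05, 1.0])
    worse = ref + 0.5 + np.random.default_rng(0).normal(0, 0.01, 5)
    same = ref.copy()
    df = compare_models({"ref": ref, "worse": worse, "same": same}, "ref")
    row_w = df[df["model"] == "worse"].iloc[0]
    row_s = df[df["model"] == "same"].iloc[0]
    assert row_w["p"] < 0.01 and row_w["t"] > 0
    assert row_s["p"] == 1.0
    assert row_w["p_bonf"] == pytest.approx(min(row_w["p"] * 2, 1.0))


def test_compare_models_drops_nan_pairs():
    ref = np.array([1.0, 1.0, 1.0, 1.0])
    other = np.array([2.0, np.nan, 2.0, 2.0])
    df = compare_models({"ref": ref, "other": other}, "ref")
    assert df.iloc[0]["n"] == 3 and df.iloc[0]["dof"] == 2


def test_compare_models_requires_reference():
    with pytest.raises(ValueError, match="reference"):
        compare_models({"a": np.ones(3)}, "b")


def test_stationarity_classify_flags():
    rng = np.random.default_rng(1)
    T = 200
    stat = rng.normal(size=T)
    walk = np.cumsum(np.random.default_rng(3).normal(size=T))
    const = np.full(T, 3.0)
    short = np.full(T, np.nan); short[:5] = rng.normal(size=5)
    X = np.column_stack([stat, walk, const, short])
    df = stationarity_classify(X)
    assert df.loc[0, "testable"] and df.loc[0, "stationary"]
    assert df.loc[1, "testable"] and not df.loc[1, "stationary"]
    assert not df.loc[2, "testable"]
    assert not df.loc[3, "testable"]


def test_run_data_ablation_shapes(short_design):
    rng = np.random.default_rng(3)
    truth = sample_ground_truth(rng, short_design, family="var")
    sched = generate_schedule(short_design, seed=5)
    study = simulate_participant(truth, sched, short_design, seed=6)
    cfg = ProtocolConfig(first_eligible_day=5, min_ema_per_day=3)
    df = run_data_ablation([study], lambda s: VAR1Forecaster(),
                           windows=(20, 30), compliance_rates=(1.0, 0.6),
                           n_repeats=2, n_test_days=2, min_step=20, cfg=cfg)
    assert set(df.columns) == {"subject", "window", "rate", "mae"}
    assert len(df) == 4  # 2 windows x 2 rates for one subject
    full = df[(df.window == 30) & (df.rate == 1.0)]["mae"].iloc[0]
    assert np.isfinite(full)


def test_run_data_ablation_requires_qualified_subject(short_design):
    rng = np.random.default_rng(4)
    truth = sample_ground_truth(rng, short_design, family="var")
    sched = generate_schedule(short_design, seed=7)
    study = simulate_participant(truth, sched, short_design, seed=8)
    with pytest.raises(ValueError, match="late eligible"):
        run_data_ablation([study], lambda s: VAR1Forecaster(),
                          n_test_days=50, min_step=10)
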