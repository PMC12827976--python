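"""Empirical proximal effects, weighted correlations and bootstraps."""

import numpy as np
import pytest
from scipy import stats

from emadyn.validation import (EmiEffectTable, empirical_proximal_effect,
                               fisher_z_aggregate, hierarchical_bootstrap,
                               null_timing_bootstrap, weighted_spearman)


def test_empirical_proximal_effect_hand_computed():
    X = np.array([[4.0, 4.0],
                  [5.0, 6.0],    # after type-0 delivery: mean change +1.5
                  [5.0, np.nan],
                  [4.0, 2.0],    # after type-1: only item 0 jointly observed, -1
                  [4.0, 2.0]])
    U = np.array([[1.0, 0.0],
                  [0.0, 0.0],
                  [0.0, 1.0],
                  [0.0, 0.0],
                  [1.0, 0.0]])   # final-row delivery is skipped
    eff, cnt = empirical_proximal_effect(X, U)
    assert eff[0] == pytest.approx(1.5)
    assert eff[1] == pytest.approx(-1.0)
    assert cnt.tolist() == [1.0, 1.0]


def test_empirical_proximal_effect_never_delivered_is_nan():
    X = np.ones((4, 2))
    U = np.zeros((4, 2))
    eff, cnt = empirical_proximal_effect(X, U)
    assert np.isnan(eff).all() and (cnt == 0).all()


def test_weighted_spearman_reduces_to_classical():
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=10), rng.normal(size=10)
    rho = weighted_spearman(a, b)
    assert rho == pytest.approx(stats.spearmanr(a, b).statistic)


def test_weighted_spearman_weights_matter():
    pred = np.array([1.0, 2.0, 3.0, 4.0])
    emp = np.array([1.0, 2.0, 4.0, 3.0])  # last two swapped
    unweighted = weighted_spearman(pred, emp)
    # down-weighting the discordant pair raises the correlation
    favored = weighted_spearman(pred, emp, np.array([5.0, 5.0, 0.5, 0.5]))
    assert favored > unweighted


def test_weighted_spearman_edge_cases():
    with pytest.raises(ValueError, match="three"):
        weighted_spearman(np.ones(2), np.ones(2))
    rho = weighted_spearman(np.array([1.0, 1.0, 1.0]),
                            np.array([1.0, 2.0, 3.0]))
    assert np.isnan(rho)  # zero-variance ranks: flagged undefined


def test_fisher_z_aggregate_mean_and_clipping():
    mean, se = fisher_z_aggregate([0.5, 0.5, 0.5])
    assert mean == pytest.approx(0.5)
    assert se == pytest.approx(0.0)
    rhos = [0.2, 0.6]
    mean2, _ = fisher_z_aggregate(rhos)
    assert mean2 == pytest.approx(np.tanh(np.mean(np.arctanh(rhos))))
    with pytest.warns(UserWarning, match="clipped"):
        fisher_z_aggregate([1.0, 0.5])
    with pytest.raises(ValueError, match="no finite"):
        fisher_z_aggregate([np.nan])


def make_table(rng, S=8, m=8, noise=0.1):
    pred = rng.normal(size=(S, m))
    emp = pred + rng.normal(0, noise, size=(S, m))
    counts = rng.integers(1, 6, size=(S, m)).astype(float)
    return EmiEffectTable(pred, emp, counts)


def test_table_validation_and_complete_subjects():
    with pytest.raises(ValueError, match="share shape"):
        EmiEffectTable(np.zeros((2, 3)), np.zeros((2, 3)), np.zeros((2, 2)))
    t = EmiEffectTable(np.zeros((2, 2)), np.zeros((2, 2)),
                       np.array([[1.0, 0.0], [2.0, 1.0]]))
    assert t.complete_subjects.tolist() == [False, True]


def test_hierarchical_bootstrap_detects_strong_association():
    rng = np.random.default_rng(1)
    table = make_table(rng, noise=0.05)
    res = hierarchical_bootstrap(table, B=300, seed=2)
    assert res["mean_rho"] > 0.8
    assert res["p"] < 0.05
    assert res["ci"][0] <= res["mean_rho"] <= res["ci"][1]


def test_hierarchical_bootstrap_null_is_inconclusive():
    rng = np.random.default_rng(3)
    pred = rng.normal(size=(8, 8))
    emp = rng.normal(size=(8, 8))  # independent of pred
    table = EmiEffectTable(pred, emp, np.ones((8, 8)))
    res = hierarchical_bootstrap(table, B=300, seed=4)
    assert res["p"] > 0.05


def test_hierarchical_bootstrap_validates_args():
    t = EmiEffectTable(np.zeros((1, 3)), np.zeros((1, 3)), np.ones((1, 3)))
    with pytest.raises(ValueError, match="two subjects"):
        hierarchical_bootstrap(t)
    t2 = EmiEffectTable(np.zeros((3, 3)), np.zeros((3, 3)), np.ones((3, 3)))
    with pytest.raises(ValueError, match="B must"):
        hierarchical_bootstrap(t2, B=10)


def simulate_timing_cohort(rng, S=6, T=80, m=5, effect=2.0):
    """Inputs with genuine type-specific one-step effects."""
    X_list, U_list, pred_list = [], [], []
    for _ in range(S):
        effects = rng.normal(0, effect, size=m)
        U = np.zeros((T, m))
        rows = rng.choice(T - 1, size=30, replace=False)
        U[rows, rng.integers(0, m, size=30)] = 1.0
        X = rng.normal(4, 0.3, size=(T, 2))
        for t in range(T - 1):
            j = np.where(U[t] == 1.0)[0]
            if j.size:
                X[t + 1] += effects[j[0]]
        X_list.append(X); U_list.append(U); pred_list.append(effects)
    return X_list, U_list, pred_list


def test_null_timing_bootstrap_significant_under_effects():
    rng = np.random.default_rng(5)
    X_list, U_list, pred_list = simulate_timing_cohort(rng)
    res = null_timing_bootstrap(X_list, U_list, pred_list, B=200, seed=6)
    assert res["observed_mean_rho"] > 0.5
    assert res["p"] < 0.05


def test_null_timing_bootstrap_conserves_delivery_counts():
    rng = np.random.default_rng(7)
    U = np.zeros((20, 3))
    U[rng.choice(20, size=8, replace=False), rng.integers(0, 3, size=8)] = 1.0
    perm = U[rng.permutation(U.shape[0])]
    assert np.allclose(perm.sum(axis=0), U.sum(axis=0))


def test_null_timing_bootstrap_warns_small_B():
    rng = np.random.default_rng(8)
    X_list, U_list, pred_list = simulate_timing_cohort(rng, S=3, T=40)
    with pytest.warns(UserWarning, match="unreliable"):
        null_timing_bootstrap(X_list, U_list, pred_list, B=50, seed=9)
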