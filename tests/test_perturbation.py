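"""Cumulative impulse responses, node targeting and EMI ranking."""

import numpy as np
import pytest

from emadyn.models import StaticBaseline, VAR1Forecaster
from emadyn.perturbation import (PerturbationInput, average_over_initials,
                                 categorize_emi_effects, design_node_input,
                                 latent_interface, observation_input_map,
                                 rank_emi_effects, selectivity_score,
                                 simulate_cir, standardize_totals)

from conftest import random_plrnn_model


def fitted_var(A, C, h=None):
    m = VAR1Forecaster()
    m.A_ = np.asarray(A, float)
    m.C_ = np.asarray(C, float)
    m.h_ = np.zeros(A.shape[0]) if h is None else np.asarray(h, float)
    m.n_items_ = A.shape[0]
    m.n_inputs_ = C.shape[1]
    return m


def test_linear_rcir_closed_form_impulse():
    """For x_{t+1} = A x_t + C u_t, the 7-step impulse rCIR is
    sum_{t=1..7} A^{t-1} C u, independent of x0 and of h."""
    A = np.array([[0.6, 0.1], [0.0, 0.5]])
    C = np.array([[1.0], [0.3]])
    m = fitted_var(A, C, h=np.array([0.2, -0.1]))
    u = np.array([2.0])
    x0 = np.array([1.0, -1.0])
    res = simulate_cir(m, u, x0, steps=7)
    expected = sum(np.linalg.matrix_power(A, t) @ C @ u for t in range(7))
    assert np.allclose(res.rcir, expected)
    # independence of the initial condition
    res2 = simulate_cir(m, u, np.zeros(2), steps=7)
    assert np.allclose(res2.rcir, res.rcir)
    # rCIR_1 is the immediate effect C u
    assert np.allclose(res.rcir1, C @ u)


def test_sustained_mode_accumulates_input():
    A = np.diag([0.5])
    C = np.array([[1.0]])
    m = fitted_var(A, C)
    u = np.array([1.0])
    imp = simulate_cir(m, u, np.zeros(1), steps=3, mode="impulse")
    sus = simulate_cir(m, u, np.zeros(1), steps=3, mode="sustained")
    # impulse: 1, .5, .25 ; sustained: 1, 1.5, 1.75
    assert imp.rcir[0] == pytest.approx(1 + 0.5 + 0.25)
    assert sus.rcir[0] == pytest.approx(1 + 1.5 + 1.75)


def test_average_over_initials_matches_single_for_linear():
    A = np.array([[0.7, 0.2], [0.1, 0.6]])
    C = np.array([[0.5, 0.0], [0.0, 1.0]])
    m = fitted_var(A, C)
    u = np.array([1.0, -1.0])
    avg = average_over_initials(m, u)
    single = simulate_cir(m, u, np.zeros(2))
    assert np.allclose(avg.rcir, single.rcir)
    assert avg.initial_conditions == "null+2 basis vectors"


def test_latent_interface_rejects_static_models():
    X = np.random.default_rng(0).normal(size=(20, 2))
    static = StaticBaseline().fit(X)
    with pytest.raises(TypeError, match="latent rollout"):
        latent_interface(static)


def test_design_node_input_maximizes_alignment():
    rng = np.random.default_rng(1)
    m = random_plrnn_model(rng)
    D = observation_input_map(m)
    target = 2
    pin = design_node_input(m, target)
    assert np.linalg.norm(pin.u) == pytest.approx(1.0)
    e = np.zeros(D.shape[0]); e[target] = 1.0

    def cosine(u):
        v = D @ u
        return (v @ e) / np.linalg.norm(v)

    best = cosine(pin.u)
    for _ in range(200):
        u = rng.normal(size=D.shape[1])
        assert cosine(u / np.linalg.norm(u)) <= best + 1e-9


def test_design_node_input_unreachable_target():
    # C maps only to latent dim 0; B row 1 reads only latent dim 1
    m = fitted_var(np.diag([0.5, 0.5]), np.array([[1.0], [0.0]]))
    with pytest.raises(ValueError, match="unreachable"):
        design_node_input(m, 1)


def test_selectivity_uniform_and_concentrated():
    D = np.eye(3)
    s = selectivity_score(D, np.array([1.0, 0.0, 0.0]))
    assert np.allclose(s, [1.0, 0.0, 0.0])
    s_unif = selectivity_score(np.ones((4, 1)), np.array([1.0]))
    assert np.allclose(s_unif, 0.25)
    with pytest.raises(ValueError, match="no observation-level effect"):
        selectivity_score(np.zeros((2, 2)), np.ones(2))


def test_rank_emi_effects_orders_by_benefit():
    # type 0 strongly positive, type 1 weakly positive, type 2 negative
    A = np.diag([0.5, 0.5])
    C = np.array([[2.0, 0.5, -1.0], [2.0, 0.5, -1.0]])
    m = fitted_var(A, C)
    df = rank_emi_effects(m)
    assert df.loc[df.emi == 0, "rank_rcir7"].iloc[0] == 1
    assert df.loc[df.emi == 2, "rank_rcir7"].iloc[0] == 3
    assert not df["tied"].any()
    with pytest.raises(ValueError, match="two intervention"):
        rank_emi_effects(fitted_var(A, C[:, :1]))


def test_rank_emi_effects_flags_exact_ties():
    A = np.diag([0.5, 0.5])
    C = np.array([[1.0, 1.0], [1.0, 1.0]])
    df = rank_emi_effects(fitted_var(A, C))
    assert df["tied"].all()
    # deterministic tiebreak by type index
    assert df["rank_rcir7"].tolist() == [1, 2]


def test_categorize_emi_effects_categories():
    rng = np.random.default_rng(2)
    S, m, n = 12, 3, 4
    R = rng.normal(0, 0.05, size=(S, m, n))
    R[:, 0, :] += 1.0       # uniformly positive
    R[:, 1, :] -= 1.0       # adverse
    df = categorize_emi_effects(R)
    assert df.loc[0, "category"] == "significantly positive"
    assert df.loc[1, "category"] == "adverse"
    assert df.loc[2, "category"] == "neutral"


def test_standardize_totals_zscores():
    z = standardize_totals(np.array([1.0, 2.0, 3.0]))
    assert z.mean() == pytest.approx(0.0)
    assert z.std() == pytest.approx(1.0)
    assert np.allclose(standardize_totals(np.full(3, 2.0)), 0.0)


def test_perturbation_input_validation():
    with pytest.raises(ValueError, match="finite"):
        PerturbationInput(u=np.array([np.nan]))
    with pytest.raises(ValueError, match="mode"):
        PerturbationInput(u=np.zeros(2), mode="ramp")
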