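import numpy as np
import pytest

from emadyn.synthetic import (GroundTruthModel, StudyDesign, generate_schedule,
                              sample_ground_truth, simulate_participant)


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def short_design():
    """Compressed study (fewer days) for fast rolling-origin tests."""
    return StudyDesign(training_days=4, assessment_days=6)


@pytest.fixture(scope="session")
def var_truth(design):
    rng = np.random.default_rng(11)
    return sample_ground_truth(rng, design, family="var")


@pytest.fixture(scope="session")
def plrnn_truth(design):
    rng = np.random.default_rng(12)
    return sample_ground_truth(rng, design, family="plrnn", latent_dim=8)


@pytest.fixture(scope="session")
def study(design, plrnn_truth):
    sched = generate_schedule(design, seed=1)
    return simulate_participant(plrnn_truth, sched, design, seed=2)


@pytest.fixture(scope="session")
def small_ssm():
    """Hand-sized linear state-space parameters for closed-form checks."""
    rng = np.random.default_rng(5)
    l, n, m = 3, 4, 2
    A = rng.normal(size=(l, l))
    A *= 0.6 / np.max(np.abs(np.linalg.eigvals(A)))
    B = rng.normal(size=(n, l))
    C = rng.normal(size=(l, m))
    h = rng.normal(size=l)
    Q = np.eye(l) * 0.4
    Gamma = np.eye(n) * 0.3
    return {"A": A, "B": B, "C": C, "h": h, "Q": Q, "Gamma": Gamma}


def make_plrnn_model(A, W1, W2, b, h, C, B, Gamma=None):
    """Assemble a PLRNNForecaster with explicit parameters (no training)."""
    from emadyn.models import PLRNNForecaster

    m = PLRNNForecaster(latent_dim=A.shape[0], hidden_dim=W2.shape[0])
    m.A_, m.W1_, m.W2_, m.b_, m.h_, m.C_, m.B_ = (np.asarray(A, float),
                                                  np.asarray(W1, float),
                                                  np.asarray(W2, float),
                                                  np.asarray(b, float),
                                                  np.asarray(h, float),
                                                  np.asarray(C, float),
                                                  np.asarray(B, float))
    m.Gamma_ = np.eye(B.shape[0]) * 0.2 if Gamma is None else np.asarray(Gamma, float)
    m.n_items_ = B.shape[0]
    m.n_inputs_ = C.shape[1]
    m.z_last_ = np.zeros(A.shape[0])
    return m


def random_plrnn_model(rng, l=4, H=6, n=5, m=3):
    A = np.diag(rng.uniform(0.2, 0.8, size=l))
    W1 = rng.normal(0, 0.4, size=(l, H))
    W2 = rng.normal(0, 0.4, size=(H, l))
    b = rng.normal(0, 0.5, size=H)
    h = rng.normal(0, 0.3, size=l)
    C = rng.normal(0, 0.5, size=(l, m))
    B = rng.normal(0, 0.6, size=(n, l))
    Gamma = np.diag(rng.uniform(0.1, 0.5, size=n))
    return make_plrnn_model(A, W1, W2, b, h, C, B, Gamma)
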