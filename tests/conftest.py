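import numpy as np
import pytest

from lvckit.model import DiabaticStateMeta, LVCModel, NormalModeBasis
from lvckit.synthetic import make_truth_model


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def truth_small():
    """A 4-state / 3-mode seeded ground-truth model."""
    return make_truth_model(n_states=4, n_modes=3, seed=11)


@pytest.fixture
def truth_paper_size():
    """A 12-state / 10-mode seeded ground-truth model."""
    return make_truth_model(n_states=12, n_modes=10, seed=5)


@pytest.fixture
def two_state_two_mode():
    """Small hand-built model used by the propagation oracles."""
    modes = NormalModeBasis(frequencies=np.array([0.15, 0.3]))
    states = (DiabaticStateMeta(label="a"), DiabaticStateMeta(label="b"))
    lam = np.zeros((2, 2, 2))
    lam[0, 0] = [0.08, -0.05]
    lam[1, 1] = [-0.06, 0.1]
    lam[0, 1] = lam[1, 0] = [0.03, 0.02]
    return LVCModel(
        modes=modes,
        states=states,
        constant_matrix=np.array([[5.0, 0.05], [0.05, 5.2]]),
        couplings=lam,
    )


def random_lvc_model(rng, n_states=3, n_modes=4, coupling_scale=0.05):
    """Unstructured random LVC model (no symmetry labels)."""
    modes = NormalModeBasis(frequencies=rng.uniform(0.05, 0.35, size=n_modes))
    states = tuple(DiabaticStateMeta(label=f"s{i}") for i in range(n_states))
    e0 = np.diag(np.sort(rng.uniform(4.5, 7.0, size=n_states)))
    off = rng.normal(0.0, coupling_scale, size=(n_states, n_states))
    e0 = e0 + np.triu(off, 1) + np.triu(off, 1).T
    lam = rng.normal(0.0, coupling_scale, size=(n_states, n_states, n_modes))
    lam = 0.5 * (lam + lam.transpose(1, 0, 2))
    return LVCModel(modes=modes, states=states, constant_matrix=e0, couplings=lam)
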