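import numpy as np
import pytest

from synchrocomp.connectome import (Connectome, assign_natural_frequencies,
                                    node_strengths, validate_connectome)
from synchrocomp.kuramoto import LorentzianSpec
from synchrocomp.synthetic_data import (CohortSpec, SyntheticConnectomeSpec,
                                        make_cohort, make_synthetic_connectome)


@pytest.fixture(scope="session")
def lorentzian_alpha():
    """The reference alpha-band Lorentzian: center 10 Hz, half-width 1 Hz."""
    return LorentzianSpec(mu=10.0, gamma=1.0)


@pytest.fixture(scope="session")
def connectome32():
    """32-node synthetic connectome used across model-side tests."""
    return make_synthetic_connectome(SyntheticConnectomeSpec(n_nodes=32, seed=0))


@pytest.fixture(scope="session")
def freqs32(connectome32):
    return assign_natural_frequencies(node_strengths(connectome32))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully analyzable synthetic cohort."""
    spec = CohortSpec(n_subjects=10, channel_count=6, n_epochs=12, seed=11)
    return spec, make_cohort(spec)


def all_to_all_connectome(n: int, distance_mm: float = 100.0) -> Connectome:
    """Fully connected unit-weight connectome with equal pair distances."""
    w = np.ones((n, n)) - np.eye(n)
    d = distance_mm * (np.ones((n, n)) - np.eye(n))
    return validate_connectome(Connectome(w, d, [f"n{i}" for i in range(n)]))
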