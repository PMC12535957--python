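import numpy as np
import pytest

from topoconnectome.netio import WeightedNetwork, default_region_labels
from topoconnectome.synthetic import SyntheticConfig, generate_cohort


def make_network(w, modality="DTI", space="raw", labels=None):
    w = np.asarray(w, dtype=float)
    labels = labels if labels is not None else default_region_labels(len(w))
    return WeightedNetwork(labels, w, modality, space)


def random_symmetric(n, rng, low=0.0, high=1.0):
    a = rng.uniform(low, high, (n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def inverted_network(w, modality="DTI"):
    return make_network(w, modality=modality, space="inverted")


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 subjects, 10 regions: fast fixture exercising every invariant."""
    return generate_cohort(SyntheticConfig(n_hv=6, n_pwms=6, parcellation_size=10, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects, 16 regions: enough signal for feature/CV tests."""
    return generate_cohort(SyntheticConfig(n_hv=10, n_pwms=10, parcellation_size=16, seed=5))
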