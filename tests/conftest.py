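import numpy as np
import pytest

from molknn.descriptors import ManyBodyParams
from molknn.synthetic import GeneratorConfig, generate_clusters, label_energies


@pytest.fixture(scope="session")
def cluster_dataset():
    """A small labelled two-level cluster dataset shared across tests."""
    cfg = GeneratorConfig(n_structures=80, seed=42)
    return label_energies(generate_clusters(cfg), cfg)


@pytest.fixture(scope="session")
def light_params():
    """Reduced-resolution descriptor parameters to keep tests fast."""
    return ManyBodyParams(cutoff=6.0, n_radial=12, n_angular=8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
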