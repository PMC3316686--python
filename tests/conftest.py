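import numpy as np
import pytest

from coraledge import read_newick
from coraledge.synth import SyntheticStudyConfig, simulate_tree


@pytest.fixture
def basic_tree():
    """((A:1,B:1):1,C:2); — the 4-edge workhorse tree."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def yule_tree():
    """Factory for reproducible pure-birth trees."""

    def make(n, seed, polytomy_fraction=0.0, missing_data_fraction=0.0):
        cfg = SyntheticStudyConfig(
            n_species=n,
            polytomy_fraction=polytomy_fraction,
            missing_data_fraction=missing_data_fraction,
            seed=seed,
        )
        return simulate_tree(cfg)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(0)
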