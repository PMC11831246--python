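import numpy as np
import pytest

from protomix.models import ItemDistances
from protomix.stimuli import build_stimulus_set
from protomix.synthetic_data import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def stimset():
    return build_stimulus_set(rng_seed=7)


@pytest.fixture(scope="session")
def transfer_distances(stimset):
    return ItemDistances.from_stimulus_set(stimset, "transfer")


@pytest.fixture(scope="session")
def training_distances(stimset):
    return ItemDistances.from_stimulus_set(stimset, "training")


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(CohortConfig(n_per_group=4, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
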