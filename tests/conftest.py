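import numpy as np
import pytest

from ringmem.io import RunConfig
from ringmem.measures import centers_frame
from ringmem.simulate import simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (4 subjects/group, 30 pairs, 12 foils) for fast
    end-to-end tests; statistical-power-sensitive tests build their own."""
    trials, designs, params = simulate_cohort(
        n_subjects={"24h": 4, "1week": 4},
        seed=7,
        design_kwargs={"n_encode_per_category": 15, "n_foils_per_category": 6},
    )
    return trials, designs, params


@pytest.fixture(scope="session")
def small_centers(small_cohort):
    return centers_frame(small_cohort[1])


@pytest.fixture
def small_config():
    return RunConfig(seed=7, n_subjects={"24h": 4, "1week": 4},
                     n_encode_per_category=15, n_foils_per_category=6)
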