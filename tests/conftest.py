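import numpy as np
import pytest

from prognoseq import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort reused by read-only tests: 200 features, 60 patients."""
    cfg = CohortConfig(
        n_patients=60,
        n_features=200,
        n_events_target=15,
        prognostic_fraction=0.1,
        block_sizes=(8,),
        block_rho=0.9,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
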