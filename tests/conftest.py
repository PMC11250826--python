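import numpy as np
import pytest

from somacohort.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-tumour synthetic cohort with default study conditions."""
    cfg = SimulationConfig(n_tumours=40)
    return generate_cohort(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
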