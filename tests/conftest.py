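import numpy as np
import pytest

from bophmars.synthetic import default_config, generate_cohort, small_config


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort (3585 smokers + 1077 nonsmokers), seed 1."""
    return generate_cohort(default_config(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Compact 800-subject, 25-predictor cohort, seed 1."""
    return generate_cohort(small_config(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
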