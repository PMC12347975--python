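import numpy as np
import pytest

from metinflam import default_config, generate_cohort_frame


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n = 246, seed 42)."""
    return generate_cohort_frame(seed=42)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with group separation removed: labels independent of labs."""
    return generate_cohort_frame(default_config().zeroed_separation(), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
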