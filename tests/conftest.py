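import numpy as np
import pytest

from mfsomics.synthdata import default_cohort_spec


@pytest.fixture(scope="session")
def spec0():
    """Default synthetic study cohort, seed 0."""
    return default_cohort_spec(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
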