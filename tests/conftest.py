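import numpy as np
import pytest

from riskcal import synthetic_data as sd
from riskcal.instrument import default_spec


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def default_cohort_df(spec):
    """Moderate default cohort used by several analysis tests."""
    params = sd.default_params(n_subjects=2000, seed=11, follow_up_range=(6.0, 25.0))
    return sd.cohort_to_frame(sd.generate_cohort(params, spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
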