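import numpy as np
import pytest

from doserr.realizations import covariance_from_cv_correlation
from doserr.synthetic import simulate_avs_like


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def avs_like_small():
    """A compact AVS-like cohort: 200 subjects, 1/12 in rho=1 groups of 10,
    dose CV 50%."""
    ids, z, triplets, groups = simulate_avs_like(200, seed=7)
    v = covariance_from_cv_correlation(z, 0.5, triplets, subject_ids=ids)
    return {"ids": ids, "z": z, "triplets": triplets, "groups": groups, "v": v}
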