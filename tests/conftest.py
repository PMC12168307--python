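import numpy as np
import pytest

from nephroradiomics.cohort import (
    CLASS_RENAL,
    coarse_grid,
    default_cohort_spec,
    generate_kidney_phantom,
)


@pytest.fixture(scope="session")
def coarse_spec():
    return default_cohort_spec(n_per_class=10, master_seed=11, grid=coarse_grid())


@pytest.fixture(scope="session")
def phantom(coarse_spec):
    return generate_kidney_phantom(coarse_spec, CLASS_RENAL, 15, 20240615)


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)
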