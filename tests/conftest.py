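import numpy as np
import pytest

from canalgrade import PhantomSpec, generate_feature_dataset, generate_study


@pytest.fixture(scope="session")
def two_level_phantom():
    """Small rendered study: severe stenosis at L4-L5, normal L3-L4."""
    spec = PhantomSpec(levels={"L4-L5": 3, "L3-L4": 0}, seed=7)
    return generate_study(spec)


@pytest.fixture(scope="session")
def feature_cohort():
    """600-level grade-conditional feature table, default severity mix."""
    return generate_feature_dataset(600, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
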