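import numpy as np
import pytest

from langscreen import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def big_cohort():
    """One large cohort shared by the slower statistical checks."""
    return generate_cohort(GeneratorConfig(n=100_000, seed=20240601))


@pytest.fixture(scope="session")
def medium_cohort():
    return generate_cohort(GeneratorConfig(n=20_000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
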