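import pytest

from t2dcea.cohort import CohortSpec, generate_population
from t2dcea.model import build_profile, load_config


@pytest.fixture(scope="session")
def cfg():
    return load_config()


@pytest.fixture(scope="session")
def profile(cfg):
    return build_profile(cfg)


@pytest.fixture(scope="session")
def population_small(cfg):
    """A small shared population for lifetime-model tests."""
    spec = CohortSpec.from_config(cfg["cohort"], n=500, seed=42)
    return generate_population(spec)
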