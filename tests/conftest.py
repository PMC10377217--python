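import dataclasses

import pytest

from lbpanomaly.cohort import CohortConfig, generate_cohort
from lbpanomaly.scoring import score_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A reduced cohort: same structure, fast to analyse."""
    return CohortConfig(n=150, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    return score_cohort(small_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort (generated once per session)."""
    return generate_cohort(CohortConfig(seed=11))


def make_cohort(**overrides):
    defaults = dict(seed=5)
    defaults.update(overrides)
    return generate_cohort(CohortConfig(**defaults))


@pytest.fixture()
def cohort_factory():
    return make_cohort


@pytest.fixture()
def config_factory():
    def _make(**overrides):
        return dataclasses.replace(CohortConfig(), **overrides)
    return _make
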