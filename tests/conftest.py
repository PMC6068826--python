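import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from stairsafe import CohortConfig, ModelParams, reference_parameter_table  # noqa: E402
from stairsafe.stability import study_sites  # noqa: E402


@pytest.fixture(scope="session")
def reference_params() -> ModelParams:
    """Study sample means: v 0.88, l 0.81, L 0.224, eta 0.11, pfc 0.08."""
    return ModelParams(v=0.88, l=0.81, L=0.224, eta=0.11, pfc=0.08)


@pytest.fixture(scope="session")
def reference_table():
    return reference_parameter_table()


@pytest.fixture(scope="session")
def sites():
    return study_sites()


@pytest.fixture()
def small_config() -> CohortConfig:
    """A fast cohort: 3 students per grade, 2 grades."""
    return CohortConfig(n_per_grade=3, grades=(1, 6), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
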