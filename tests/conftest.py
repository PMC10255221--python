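import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fishspec import StudyConfig, make_aging_params, mode_wavelengths, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def aging_model():
    return make_aging_params("sablefish", seed=1)


@pytest.fixture(scope="session")
def fl_wavelengths():
    return mode_wavelengths("FL")


@pytest.fixture(scope="session")
def small_study():
    """A small but fully structured multi-mode study (2 fillets, 6 days)."""
    return simulate_study(StudyConfig(voxels_per_fillet_day=25), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
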