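import warnings

import pytest
from hypothesis import HealthCheck, settings

import pulsetox as pt

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# arviz emits a refactor FutureWarning on import; irrelevant to the suite
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def design():
    return pt.ExposureDesign()


@pytest.fixture(scope="session")
def gen_config():
    return pt.GeneratorConfig()


@pytest.fixture(scope="session")
def dataset(gen_config, design):
    """One full simulated dataset at the default study design."""
    return pt.simulate_dataset(gen_config, design, seed=123)


@pytest.fixture(scope="session")
def on_curve():
    return pt.BROOD_ON_DOSE


@pytest.fixture(scope="session")
def total_curve():
    return pt.BROOD_PULSE_TOTAL
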