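import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sdtsim import ObserverParams, StimulusSet, get_preset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def f2_limits() -> tuple[ObserverParams, float]:
    """Fitted ferret-F2 Method-of-Limits observer and its masker level."""
    return get_preset("F2", "limits")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_params() -> ObserverParams:
    """A clean observer: no bias, no guessing, no history shifts."""
    return ObserverParams(internal_sd=9.2, reference_level=37.35)


@pytest.fixture
def single_level_stim() -> StimulusSet:
    return StimulusSet("limits", (47.35,), noise_level=48.0)
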