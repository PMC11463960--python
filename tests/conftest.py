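import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bovine():
    """Bovine-style nuclease target: amplicon, guide, transcript, isoforms."""
    from embryoedit import fixtures as f

    return {
        "amplicon": f.bovine_amplicon(),
        "guide": f.bovine_guide(),
        "transcript": f.bovine_transcript(),
        "isoforms": f.bovine_isoforms(),
    }


@pytest.fixture
def rabbit():
    """Rabbit-style base-editor target: amplicon, guide, transcript, isoforms."""
    from embryoedit import fixtures as f

    return {
        "amplicon": f.rabbit_amplicon(),
        "guide": f.rabbit_guide(),
        "transcript": f.rabbit_transcript(),
        "isoforms": f.rabbit_isoforms(),
    }
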