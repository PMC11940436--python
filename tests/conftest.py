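import numpy as np
import pytest

from mcd.synth import SynthSpec, generate_session


@pytest.fixture(scope="session")
def short_runner_session():
    """~24 s runner session (32 ch) used by several integration tests."""
    return generate_session(SynthSpec(session_minutes=0.4, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
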