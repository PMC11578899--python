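import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import noveltytask as nt

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_session() -> nt.Session:
    """One full default session from a generative RW/softmax agent."""
    rng = np.random.default_rng(12345)
    agent = nt.SoftmaxAgent(nt.AgentParams(alpha=0.692, beta=15.0))
    return nt.run_session(agent, nt.SessionConfig(), rng)


@pytest.fixture(scope="session")
def augmented_events(default_session):
    """Default session events with ev_chosen / rpe / explore columns."""
    return nt.augment_events(default_session, params=nt.AgentParams(alpha=0.692, beta=15.0))


def simulate_session(seed: int, alpha: float = 0.692, beta: float = 15.0, **config_kwargs):
    rng = np.random.default_rng(seed)
    agent = nt.SoftmaxAgent(nt.AgentParams(alpha=alpha, beta=beta))
    return nt.run_session(agent, nt.SessionConfig(**config_kwargs), rng)
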