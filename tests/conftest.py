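import pytest

from gainloss import AgentParams, TaskConfig, build_session, simulate_agent


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def schedule(config):
    return build_session(config, seed=7)


@pytest.fixture(scope="session")
def played_session(schedule):
    """A moderately learning agent's session, reused across read-only tests."""
    params = AgentParams(alpha_gain=0.3, alpha_loss=0.2, beta=0.3, r0=0.5)
    return simulate_agent(schedule, params, seed=42)
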