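import numpy as np
import pytest

from blockprior import TaskConfig, generate_session
from blockprior.agents import AgentParams, simulate_agent


@pytest.fixture(scope="session")
def default_config() -> TaskConfig:
    return TaskConfig(n_trials=400)


@pytest.fixture(scope="session")
def session_table(default_config):
    return generate_session(default_config, seed=11, session_id="s0", mouse_id="m0")


@pytest.fixture(scope="session")
def toy_config() -> TaskConfig:
    """Tiny block structure amenable to brute-force enumeration."""
    return TaskConfig(gamma=0.7, tau_block=2.0, block_min=1, block_max=2,
                      n_unbiased=0, n_trials=6)


def simulate_cohort(n_mice, sessions_per_mouse, agent: AgentParams, seed,
                    n_trials=645):
    """Simulated multi-mouse cohort used by several behavioural tests."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    cfg = TaskConfig(n_trials=n_trials)
    tables = []
    for m in range(n_mice):
        for s in range(sessions_per_mouse):
            t = generate_session(cfg, seed=int(rng.integers(2**31)),
                                 session_id=f"m{m}s{s}", mouse_id=f"m{m}")
            sim, _ = simulate_agent(t, agent, seed=int(rng.integers(2**31)))
            tables.append(sim)
    return pd.concat(tables, ignore_index=True)
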