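import numpy as np
import pytest

from breathlearn import learning_models as lm
from breathlearn import task_sim


@pytest.fixture(scope="session")
def default_schedule():
    return task_sim.generate_blt_schedule(seed=1)


@pytest.fixture(scope="session")
def contingency(default_schedule):
    return lm.encode_contingency_space(default_schedule)


@pytest.fixture(scope="session")
def rw_cohort(default_schedule):
    """15 simulated RW subjects at alpha=0.3, zeta=5 (shared across tests)."""
    specs = [task_sim.AgentSpec("RW", 0.3, 5.0, seed=100 + i) for i in range(15)]
    out = []
    for spec in specs:
        y, traj, inp = task_sim.simulate_agent(default_schedule, spec)
        out.append((y, traj, inp))
    return out
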