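import numpy as np
import pytest

from advicehgf import hgf, task


@pytest.fixture(scope="session")
def default_design():
    return task.make_task_design()


@pytest.fixture(scope="session")
def short_design():
    # 30-trial design for fast fitting tests: 10 stable + 20 volatile
    return task.make_task_design(
        n_trials=30, blocks=[(10, 0.9), (10, 0.2), (10, 0.8)], rng=3,
        probe_trials=[5, 15, 25],
    )


@pytest.fixture(scope="session")
def played_session(default_design):
    inputs = task.sample_advice_outcomes(default_design, 11)
    agent = hgf.AgentParams()
    return hgf.simulate_choices(
        agent, inputs.u, inputs.c, variant="mean_reverting", rng=12,
        phase=default_design.phase,
    )


@pytest.fixture()
def rng():
    # fresh per test so draws do not depend on suite composition/order
    return np.random.default_rng(2024)
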