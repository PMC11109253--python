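import numpy as np
import pytest

import tigermaze as tm


@pytest.fixture(scope="session")
def maze():
    return tm.reference_maze()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort(maze):
    """Eight synthetic participants under the default study conditions
    (hierarchical generator at the reported mean parameters, default
    policy, 24 games each)."""
    return tm.simulate_cohort(8, tm.ModelParams(), tm.AgentPolicy(), maze,
                              n_games=24, seed=2024)


@pytest.fixture(scope="session")
def one_participant(maze):
    """A single clean participant (no missed responses) for replay and
    fitting tests."""
    policy = tm.AgentPolicy(miss_rate=0.0)
    return tm.simulate_participant(tm.ModelParams(), policy, maze,
                                   n_games=12, seed=77)


def random_belief(rng, maze):
    p_grid = rng.dirichlet(np.ones(maze.n_cells))
    anchor = rng.dirichlet(np.ones(maze.n_cells))
    p_tiger = rng.dirichlet(np.ones(3))
    return tm.Belief(p_tiger, p_grid, anchor, 0)
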