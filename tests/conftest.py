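import numpy as np
import pytest

from rehabgym import Schedule, TrainingBlock, equal_curve_scenario, validate_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_blocks(scenario, rng, max_blocks=6):
    """A random block set (feasible or not): random distinct pairs with
    random intervals inside the session."""
    n_pairs = scenario.n_patients * scenario.n_robots
    k = int(rng.integers(0, min(max_blocks, n_pairs) + 1))
    pair_ids = rng.choice(n_pairs, size=k, replace=False)
    blocks = []
    for pid in pair_ids:
        p = int(pid) // scenario.n_robots + 1
        r = int(pid) % scenario.n_robots + 1
        s = int(rng.integers(1, scenario.H + 1))
        e = int(rng.integers(s, scenario.G + 1))
        blocks.append(TrainingBlock(p, r, s, e))
    return Schedule(tuple(blocks))


def random_feasible_schedule(scenario, rng, max_blocks=6, tries=200):
    """Rejection-sample a feasible random schedule (possibly empty)."""
    for _ in range(tries):
        schedule = random_blocks(scenario, rng, max_blocks)
        if validate_schedule(scenario, schedule).feasible:
            return schedule
    return Schedule(())


@pytest.fixture
def gym_5p5r7t():
    return equal_curve_scenario(5, 5, 7)


@pytest.fixture
def gym_5p5r12t_exit():
    return equal_curve_scenario(5, 5, 12, exit_time=1)
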