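import numpy as np
import pytest

from rewardremap import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact switch session with all tuning classes (shared, read-only)."""
    cfg = SimConfig(
        seed=7, n_trials=40, switch_trial=20,
        population_spec={
            "TR": {"n": 12}, "RR": {"n": 12}, "untuned": {"n": 4},
            "appearing": {"n": 4}, "disappearing": {"n": 4},
            "speed_coupled": {"n": 2},
        },
    )
    return simulate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
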