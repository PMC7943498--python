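import numpy as np
import pandas as pd
import pytest

from abpbench import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def session(default_config):
    """One simulated 1 h session shared across read-only tests."""
    return simulate_session(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_minutes(rng, n=50, start_min=1):
    """A plausible per-minute vitals table for feature/oracle tests."""
    sbp = rng.normal(120, 10, n)
    dbp = rng.normal(60, 6, n)
    return pd.DataFrame({
        "t_end_s": (np.arange(n) + start_min) * 60,
        "sbp": sbp,
        "dbp": dbp,
        "map": dbp + (sbp - dbp) / 3,
        "hr": rng.normal(70, 8, n),
        "n": 12,
    })
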