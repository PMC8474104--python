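import numpy as np
import pytest

from delcall.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Moderately sized cohort with the default (recurrent-origin) structure."""
    return simulate_dataset(SimulationConfig(n_individuals=800, seed=3))


@pytest.fixture(scope="session")
def single_origin_dataset():
    """One deletion origin, no copying switches: perfect local LD."""
    cfg = SimulationConfig(n_individuals=500, n_del_origins=1,
                           copy_switch_scale=0.0, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
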