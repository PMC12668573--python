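import numpy as np
import pytest

from agrimeta import SimConfig, observation_effects, simulate_database


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_sites=30, n_obs=200, seed=11)


@pytest.fixture(scope="session")
def small_db(small_config):
    db, truth = simulate_database(small_config)
    return db, truth


@pytest.fixture(scope="session")
def small_obs(small_db):
    db, _ = small_db
    return observation_effects(db)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260904)
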