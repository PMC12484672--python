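import numpy as np
import pytest

from tectolearn.task_design import DesignConfig, generate_session


@pytest.fixture(scope="session")
def default_session():
    """The published 288-trial presented / 216-trial analyzed design."""
    return generate_session(DesignConfig())


@pytest.fixture(scope="session")
def toy_config():
    """A reduced design (24-trial blocks, 2 aversive types) for fast runs."""
    return DesignConfig(
        trials_per_block=24,
        volatile_block_len=8,
        volatile_probs=(1 / 4, 1 / 2, 3 / 4),
        n_aversive_types=2,
    )


@pytest.fixture(scope="session")
def toy_session(toy_config):
    return generate_session(toy_config)


@pytest.fixture(scope="session")
def default_hgf(default_session):
    from tectolearn.hgf import run_hgf, subset_aversive

    traj = run_hgf(default_session.contingency_vector())
    return {"all": traj, "aversive": subset_aversive(traj, default_session)}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
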