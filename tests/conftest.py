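import numpy as np
import pytest

from pilnc.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A reduced-scale synthetic study shared across unit tests."""
    cfg = SimConfig(
        seed=11,
        n_coding=40,
        n_tair10_lnc=10,
        n_pseudo=4,
        n_te=4,
        n_novel=60,
        n_mirna=3,
        n_planted_targets=4,
        n_planted_mimics=2,
        n_planted_negatives=2,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The generator at its default study conditions."""
    return simulate(SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
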