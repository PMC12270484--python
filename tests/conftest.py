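import numpy as np
import pytest

from ideadna import synthfix


@pytest.fixture(scope="session")
def scenario16():
    """Planted scenario at the standard benchmark size (30 aa, 16 nt, 40 contacts)."""
    return synthfix.planted_scenario(11)


@pytest.fixture(scope="session")
def trained16(scenario16):
    model, stats = synthfix.train_planted(scenario16, seed=11)
    return model, stats


@pytest.fixture(scope="session")
def scenario8():
    """Scenario with an 8-nt threading strand, sized for genome scans."""
    return synthfix.planted_scenario(8, n_dna=8)


@pytest.fixture(scope="session")
def trained8(scenario8):
    model, stats = synthfix.train_planted(scenario8, seed=8)
    return model, stats


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
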