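import numpy as np
import pytest

import bulbgenesis as bg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def symmetric4_train():
    """Training ensemble: the two similar pairs collapsed (delta = 0)."""
    return bg.generate_symmetric4(0.0)


@pytest.fixture(scope="session")
def symmetric4_probe():
    return bg.generate_symmetric4(0.2)


@pytest.fixture(scope="session")
def odor_set():
    return bg.synthetic_odor_set(seed=0)


@pytest.fixture(scope="session")
def natural_ensemble(odor_set):
    names = ["limonene_plus", "limonene_minus", "carvone_plus",
             "carvone_minus", "butanol", "hexanol", "heptanol", "acetic_acid"]
    return bg.StimulusEnsemble([odor_set[n] for n in names])


@pytest.fixture(scope="session")
def small_network():
    """A small random reciprocal network on 10 mitral cells."""
    rng = np.random.default_rng(7)
    net = bg.NetworkState.empty(10, spontaneous=0.1)
    return net.add_granule_cells(40, connections_per_cell=3,
                                 inh_weight=0.02, rng=rng)
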