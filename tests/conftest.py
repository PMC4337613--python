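import numpy as np
import pytest

from mpskel import LatticeConfig, make_trace, simulate_lattice


@pytest.fixture(scope="session")
def straight_trace():
    """30 µm straight axon trace along +x."""
    return make_trace(30.0, 0.0)


@pytest.fixture(scope="session")
def default_lattice(straight_trace):
    """Default periodic-lattice localization table, seed 1."""
    return simulate_lattice(straight_trace, LatticeConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
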