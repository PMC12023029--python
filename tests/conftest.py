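import numpy as np
import pytest

from ionsyn.presets import CONDITION_PRESETS
from ionsyn.sans import generate_pool
from ionsyn.synthetic_data import make_toy_trajectory


@pytest.fixture(scope="session")
def small_pool():
    """300-chain, 140-residue conformer pool shared across scattering tests."""
    return generate_pool(140, 300, seed=1)


@pytest.fixture(scope="session")
def tiny_pool():
    """40-chain, 30-residue pool small enough for exhaustive enumeration."""
    return generate_pool(30, 40, seed=4)


@pytest.fixture(scope="session")
def na_ca_trajectory():
    """Toy trajectory with both ion species, shared across metric tests."""
    traj, truth = make_toy_trajectory(
        CONDITION_PRESETS["na_ca"], n_residues=140, n_frames=301, n_waters=150, seed=2
    )
    return traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
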