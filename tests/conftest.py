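import numpy as np
import pytest

from astromigrate.config import AnalysisConfig, SimulationConfig
from astromigrate import synthetic


@pytest.fixture(scope="session")
def ana():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def sim_small():
    """A small but fully featured simulation setup."""
    return SimulationConfig(seed=11, field_size_um=(150.0, 150.0, 40.0),
                            n_cells_per_mode=5, vessel_n_segments=10)


@pytest.fixture(scope="session")
def network_small(sim_small):
    return synthetic.generate_vessel_network(sim_small)


@pytest.fixture(scope="session")
def mask_small(sim_small, network_small, ana):
    from astromigrate.vessels import build_vessel_mask

    stack = synthetic.rasterize(network_small, [], 0, sim_small)
    return build_vessel_mask(stack, "vessels", sim_small.channel_amplitude / 2.0, ana)


def random_track(rng, n=20, hemisphere="right", dt=0.25, scale=30.0):
    """An unconstrained random test track (not from the simulator)."""
    from astromigrate.datatypes import Track

    t = np.arange(n) * dt
    xyz = np.cumsum(rng.normal(0.0, scale * dt, size=(n, 3)), axis=0) + 100.0
    return Track(track_id="rnd", hemisphere=hemisphere, t_h=t, xyz_um=xyz)
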