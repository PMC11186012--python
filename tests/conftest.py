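import numpy as np
import pytest

import memsolute as ms


@pytest.fixture(scope="session")
def toy_bilayer():
    """Jitter-free 10x10-per-leaflet lattice bilayer, membrane-centred."""
    traj = ms.gen_toy_bilayer(100, apl=0.700, pn_tilt_deg=68.7,
                              ch_polar_deg=90.0, jitter=0.0, seed=11)
    return ms.center_on_membrane(traj)


@pytest.fixture(scope="session")
def two_well_pmf():
    """Membrane-like PMF: barrier at the centre, well at 1.0 nm, surface
    shoulder, flat water plateau beyond 4 nm."""
    z = np.array([0.0, 0.5, 1.0, 1.5, 2.25, 2.75, 4.0, 7.0])
    g = np.array([20.0, 8.0, 0.0, 1.0, 5.0, 3.5, 6.0, 6.0])
    return ms.PmfSpec(z, g, temperature=310.15)


@pytest.fixture(scope="session")
def langevin_samples(two_well_pmf):
    return ms.gen_langevin_z(two_well_pmf, D=1.0, dt=1.0, n_steps=10 ** 6,
                             seed=42)
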