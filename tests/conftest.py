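import numpy as np
import pytest

from toothtrack.grids import Grid, Isoscape
from toothtrack import synthetic


@pytest.fixture
def two_patch_isoscape():
    """16x16 world split into two lithological halves: 0.711 (west) and
    0.713 (east), tiny uniform SD, 2 km cells."""
    mean = np.full((16, 16), 0.711)
    mean[:, 8:] = 0.713
    sd = np.full((16, 16), 1e-4)
    return Isoscape(Grid(mean, 2000.0), Grid(sd, 2000.0))


@pytest.fixture
def uniform_isoscape():
    mean = np.full((12, 12), 0.7115)
    sd = np.full((12, 12), 5e-4)
    return Isoscape(Grid(mean, 2000.0), Grid(sd, 2000.0))


@pytest.fixture
def two_patch_env(two_patch_isoscape):
    """Quarterly rounds between one camp per patch over five years."""
    camps = [(4000.0, 4000.0, 1800.0), (20000.0, 20000.0, 2400.0)]
    sched = synthetic.make_seasonal_schedule(camps, moves_per_year=4, n_years=5)
    env = synthetic.simulate_environment(sched, two_patch_isoscape)
    return sched, env


@pytest.fixture
def identity_curve():
    """Synthetic calibration curve mu(theta) = theta with zero curve error."""
    return synthetic.synthetic_curve(2000, 4000, sigma=0.0)


@pytest.fixture
def wiggly_curve():
    return synthetic.synthetic_curve(2500, 3500, wiggle_amp=8.0,
                                     wiggle_period=150.0, sigma=8.0)
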