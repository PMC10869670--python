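import numpy as np
import pytest

from sdsa.frr import FrrScheme
from sdsa.io import FrameStack
from sdsa.model import GVParams, TimeGrid, sample_curve
from sdsa.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free 24x24x16 phantom with ground truth (seed 5)."""
    return generate_phantom(PhantomSpec(shape=(24, 24), seed=5, noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """24x24x16 phantom with 2% noise (seed 7)."""
    return generate_phantom(PhantomSpec(shape=(24, 24), seed=7, noise_sigma=0.02))


@pytest.fixture
def exact_voxel_series():
    """Noise-free gamma-variate series spanning arrival and peak.

    8 samples at 0.5-s spacing for GVParams(50, 2, 1.5, AT=2); times start
    at 1.5 s so both the arrival (2 s) and the peak (Tmax = 5 s) lie on the
    grid.
    """
    params = GVParams(50.0, 2.0, 1.5, 2.0)
    times = 1.5 + 0.5 * np.arange(8)
    grid = TimeGrid(8, 2.0, origin=1.5)
    return times, sample_curve(params, grid), params


def n_informative_reduced_samples(truth_params, reduced_grid) -> int:
    """Number of retained samples strictly after a voxel's arrival time."""
    return int((reduced_grid.times > truth_params.arrival_time).sum())
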