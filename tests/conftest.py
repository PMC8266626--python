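import numpy as np
import pytest

import heliquant as hq


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """Noise-free single-dye configuration for exactness tests."""
    return hq.SimConfig(seed=1, n_frames=50, read_noise_sd=0.0,
                        background_rate=0.0, offset=0.0,
                        bleach_tau=float("inf"), dol_lambda=0.0)


@pytest.fixture
def calib():
    """A plain labelling calibration: 100-count fluorophores, lambda = 3."""
    return hq.LabelingCalibration(single_fluor_intensity_mean=100.0,
                                  single_fluor_intensity_sd=10.0,
                                  dol_lambda=3.0)


def make_trajectory(intensities, dt=1.0):
    intensities = np.asarray(intensities, dtype=float)
    return hq.IntensityTrajectory(times=np.arange(intensities.size) * dt,
                                  intensities=intensities)
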