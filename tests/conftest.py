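import numpy as np
import pytest

from gaitvel import SimulationConfig, simulate_cohort, simulate_trial


@pytest.fixture(scope="session")
def small_cfg():
    """Small but fully featured cohort configuration for fast tests."""
    return SimulationConfig(n_subjects=3, n_strides=25, seed=7)


@pytest.fixture(scope="session")
def trial(small_cfg):
    return simulate_trial(small_cfg, subject_id="S00", subject_index=0)


@pytest.fixture(scope="session")
def noise_free_cfg():
    """Zero sensor and target noise; natural gait variability retained."""
    return SimulationConfig(
        n_subjects=3,
        n_strides=20,
        accel_noise_sd=0.0,
        gyro_noise_sd=0.0,
        apv_model={"noise_sd": 0.0},
        seed=11,
    )


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_cfg):
    return simulate_cohort(noise_free_cfg)


@pytest.fixture(scope="session")
def grid_cfg():
    """Noise-free and fully regular: every stride lasts exactly 1.1 s = 110
    samples, so stride slices tile the sample grid and Fourier projection is
    exact to machine precision."""
    return SimulationConfig(
        n_subjects=2,
        n_strides=15,
        stride_time_cv=0.0,
        mean_stride_time=1.1,
        event_fraction_jitter_sd=0.0,
        stride_amp_cv=0.0,
        accel_noise_sd=0.0,
        gyro_noise_sd=0.0,
        apv_model={"noise_sd": 0.0},
        seed=13,
    )


@pytest.fixture(scope="session")
def grid_trial(grid_cfg):
    return simulate_trial(grid_cfg, subject_id="S00", subject_index=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
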