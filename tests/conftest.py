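import numpy as np
import pytest

from gaitforce import synthetic


@pytest.fixture(scope="session")
def default_config():
    return synthetic.GeneratorConfig()


@pytest.fixture(scope="session")
def zero_noise_config():
    return synthetic.GeneratorConfig(noise_sd_accel=0.0, noise_sd_gyro=0.0)


@pytest.fixture(scope="session")
def mean_config():
    """All population SDs zero: every subject equals the population mean."""
    return synthetic.GeneratorConfig(
        mass_sd=0.0, stance_sd=0.0, gain_sd=0.0, impact_gain_sd=0.0,
        cycle_scale_sd=0.0, mount_rot_sd_deg=0.0,
        noise_sd_accel=0.0, noise_sd_gyro=0.0)


@pytest.fixture(scope="session")
def default_subject(default_config):
    return synthetic.make_subject(7, default_config)


@pytest.fixture(scope="session")
def quiet_subject(zero_noise_config):
    return synthetic.make_subject(7, zero_noise_config)


@pytest.fixture(scope="session")
def quiet_trial(quiet_subject):
    """Noise-free 20 s trial at 1.0 m/s."""
    return synthetic.simulate_trial(quiet_subject, 1.0, 20.0, 100.0)


@pytest.fixture(scope="session")
def noisy_trial(default_subject):
    return synthetic.simulate_trial(default_subject, 1.0, 20.0, 100.0)


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """3 subjects x 2 speeds x 10 s, default noise."""
    return synthetic.simulate_cohort(3, [0.7, 1.3], 10.0, seed=11,
                                     config=default_config)
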