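import numpy as np
import pytest

from leafactin.simulate import KineticParams, SimConfig, simulate_reduced
from leafactin.spectrum import default_cross_section_spectrum

#: the nine photon-flux levels (E m^-2 s^-1) of a typical blue-light
#: calibration series spanning 0.3-7.8 mE m^-2 s^-1
CALIBRATION_INTENSITIES = [
    0.3e-3, 1.2e-3, 2.4e-3, 3.5e-3, 4.6e-3, 5.5e-3, 6.4e-3, 7.2e-3, 7.8e-3,
]


@pytest.fixture(scope="session")
def packaged_spectrum():
    return default_cross_section_spectrum()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reduced_sim():
    """A clean reduced-model trace at sigma*I ~ 4785 s^-1 (tau ~ 209 us)."""
    params = KineticParams(sigma=1.1e6, k_reduced=100.0)
    config = SimConfig(intensity=4.35e-3, duration_s=6e-3, pre_onset_s=6e-4,
                       n_points=150_000, noise_sd_rel=0.01, seed=7)
    return simulate_reduced(params, config)
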