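import numpy as np
import pytest

from odovis.spectra import AbsorbanceSpectrum, template_sensitivity
from odovis.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def wl():
    """Standard 1-nm wavelength grid, 300-700 nm."""
    return np.arange(300.0, 701.0, 1.0)


@pytest.fixture
def clean_spectrum(wl):
    """Factory: noiseless template-shaped absorbance spectrum."""

    def make(lambda_max=543.0, label="pigment"):
        return AbsorbanceSpectrum(wl, template_sensitivity(lambda_max, wl), label=label)

    return make


@pytest.fixture
def noisy_spectrum(wl):
    """Factory: template plus Gaussian noise with a given seed."""

    def make(lambda_max=543.0, sd=0.02, seed=0):
        rng = np.random.default_rng(seed)
        y = template_sensitivity(lambda_max, wl) + rng.normal(0.0, sd, wl.size)
        return AbsorbanceSpectrum(wl, y, label="noisy")

    return make


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=1)
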