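import numpy as np
import pytest

from brixcal.containers import ReferenceVector, SpectraMatrix
from brixcal.simulate import SyntheticConfig, default_wavelength_grid, generate_dataset


@pytest.fixture(scope="session")
def grid():
    return default_wavelength_grid()


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 100 samples on the 486-band grid."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_spectra(rng):
    """A small random spectra matrix on a uniform grid."""
    wavelengths = np.linspace(500.0, 900.0, 40)
    values = 0.5 + 0.1 * rng.standard_normal((12, 40))
    return SpectraMatrix(wavelengths, values)


def make_clean_config(**overrides):
    """A noiseless, scatter-free configuration (pure Beer-Lambert)."""
    base = dict(
        scatter_gain_range=(1.0, 1.0),
        scatter_offset_sd=0.0,
        baseline_amplitude=0.0,
        noise_sd=0.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture()
def clean_config():
    return make_clean_config()
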