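import numpy as np
import pytest

from thrombospec import synthetic_data
from thrombospec.spectral_io import DEFAULT_WAVELENGTHS


@pytest.fixture(scope="session")
def basis():
    return synthetic_data.make_basis_spectra(seed=0)


@pytest.fixture(scope="session")
def small_grid():
    return np.linspace(470.0, 900.0, 20)


@pytest.fixture(scope="session")
def small_basis(small_grid):
    return synthetic_data.make_basis_spectra(small_grid, seed=0)


@pytest.fixture(scope="session")
def noiseless_scene(basis):
    scene = synthetic_data.default_scene(32, 32, noise_sd=0.0, seed=1)
    return synthetic_data.make_cube(scene, basis)


@pytest.fixture(scope="session")
def default_grid():
    return DEFAULT_WAVELENGTHS
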