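import numpy as np
import pytest

from lfrecon.optics import OpticalConfig, build_psf


@pytest.fixture(scope="session")
def toy_optics() -> OpticalConfig:
    """Small N=4 geometry used throughout the desk-scale tests."""
    return OpticalConfig(
        pixels_per_lenslet=4, z_planes=(-4.0, -2.0, 0.0, 2.0, 4.0),
        kernel_halfwidth=1, lenslet_pitch=1.0, numerical_aperture=1.0,
        medium_index=1.33, gauss_sigma0=0.3, gauss_sigma_slope=0.03,
        disparity_slope=0.12)


@pytest.fixture(scope="session")
def toy_psf(toy_optics):
    return build_psf(toy_optics)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
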