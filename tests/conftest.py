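import numpy as np
import pytest

from datnorm import ScannerModel, build_phantom_spec, rasterize_phantom
from datnorm.scanner import ConditionBias


@pytest.fixture(scope="session")
def phantom_spec_84():
    """8:1 right / 4:1 left phantom at 5 kBq/mL background."""
    return build_phantom_spec(8.0, 4.0, 5.0)


@pytest.fixture(scope="session")
def phantom_84(phantom_spec_84):
    """Noiseless unblurred rasterization at 2 mm voxels."""
    return rasterize_phantom(phantom_spec_84, 2.0)


@pytest.fixture(scope="session")
def uniform_phantom():
    return rasterize_phantom(build_phantom_spec(1.0, 1.0, 5.0), 2.0)


@pytest.fixture(scope="session")
def identity_scanner():
    """No PSF, no bias, no noise: acquisition is the identity."""
    return ScannerModel(
        name="ideal",
        voxel_size=2.0,
        psf_fwhm=0.0,
        condition_bias={"I": ConditionBias()},
        noise_scale=None,
    )


@pytest.fixture(scope="session")
def blurred_scanner():
    """9 mm FWHM PSF, no bias, no noise."""
    return ScannerModel(
        name="blurred",
        voxel_size=2.0,
        psf_fwhm=9.0,
        condition_bias={"I": ConditionBias()},
        noise_scale=None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
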