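import numpy as np
import pytest

from pkradiomics import PhantomSpec, simulate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """A fast phantom: ~123-voxel lesion on a 16^3 grid."""
    return PhantomSpec(grid_shape=(16, 16, 16), lesion_center=(8, 8, 8),
                       lesion_radius=4.6, spacing=(1.5, 1.5, 1.5),
                       noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return simulate_phantom(small_spec)


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless phantom at the default cohort geometry (~1000-voxel lesion)."""
    return simulate_phantom(PhantomSpec(noise_sd=0.0, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
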