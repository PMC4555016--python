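import numpy as np
import pytest

from brainclass import PhantomSpec, ROISpec, generate_phantom


@pytest.fixture()
def rng():
    """Fresh, identically-seeded generator per test for order-independence."""
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A quick phantom with a clear GM-channel effect (16^3 grid)."""
    return PhantomSpec(grid_shape=(16, 16, 16), voxel_size_mm=2.0,
                       n_per_group=(10, 10),
                       effect_rois=(ROISpec((8, 8, 8), 6.0, 0.5),),
                       noise_sd=0.05, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return generate_phantom(small_phantom_spec)
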