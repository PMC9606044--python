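import numpy as np
import pytest

from ambarpet.core import Volume
from ambarpet.phantom import PhantomSpec, build_phantom


SMALL_GRID = (24, 28, 24)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale phantom used across the suite."""
    return PhantomSpec(grid_shape=SMALL_GRID, n_regions=12, cerebellum_region_ids=(1,),
                       ad_region_ids=(3, 4), seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return build_phantom(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_volume(data, voxel=4.0, tag="phantom") -> Volume:
    return Volume(np.asarray(data, dtype=float), (voxel,) * 3, tag)
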