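import numpy as np
import pytest

from scalescape import ClassRaster
from scalescape.synthetic import (
    CommunityParams,
    LandscapeParams,
    generate_landscape,
    place_sites,
    simulate_community,
)


@pytest.fixture(scope="session")
def landscape_bundle():
    """One mid-sized synthetic mosaic shared across the suite."""
    params = LandscapeParams(shape=(1500, 1500), n_blocks=150)
    raster, table = generate_landscape(params, seed=42)
    return raster, table


@pytest.fixture(scope="session")
def sites40(landscape_bundle):
    raster, _ = landscape_bundle
    return place_sites(raster, 40, seed=7)


@pytest.fixture(scope="session")
def surveys40(landscape_bundle, sites40):
    raster, table = landscape_bundle
    surveys, truth = simulate_community(
        raster, sites40, CommunityParams(), seed=99, table=table
    )
    return surveys, truth


def make_raster(grid, cell=5.0, origin=(0.0, 0.0), nodata=-9999):
    return ClassRaster(
        grid=np.asarray(grid, dtype=np.int32),
        cell_size=cell,
        origin=origin,
        nodata=nodata,
    )


@pytest.fixture
def uniform_raster():
    return make_raster(np.ones((20, 20)))


@pytest.fixture
def half_split_raster():
    """100x100 grid at 5 m cells split by one straight vertical boundary: 25 ha."""
    g = np.ones((100, 100))
    g[:, 50:] = 2
    return make_raster(g)


@pytest.fixture
def checkerboard_raster():
    g = (np.indices((100, 100)).sum(axis=0) % 2) + 1
    return make_raster(g)
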