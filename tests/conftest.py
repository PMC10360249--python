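import numpy as np
import pytest
from shapely import MultiPoint, voronoi_polygons
from shapely.geometry import box

from bymap.bym_inference import BYMData, BYMModelSpec, fit
from bymap.spatial_lattice import build_adjacency, square_grid_lattice
from bymap.synthetic_city import generate_city

# fast sampler settings shared by fitting tests
FAST_FIT = dict(n_chains=2, n_draws=300, n_warmup=300)


def random_voronoi(n, seed, bbox=(0.0, 0.0, 100.0, 100.0), scheme="queen"):
    """Random Voronoi lattice built directly (independent of the
    synthetic_city generator) for geometry oracles."""
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = bbox
    pts = np.column_stack(
        [rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)]
    )
    frame = box(*bbox)
    cells = voronoi_polygons(MultiPoint(pts), extend_to=frame, ordered=True)
    polys = [c.intersection(frame) for c in cells.geoms]
    ids = [f"V{i:03d}" for i in range(n)]
    return build_adjacency(ids, polys, scheme, warn_islands=False)


@pytest.fixture(scope="session")
def grid3():
    return square_grid_lattice(3, 3, "queen")


@pytest.fixture(scope="session")
def grid5_rook():
    return square_grid_lattice(5, 5, "rook")


@pytest.fixture(scope="session")
def small_city():
    return generate_city(n_areas=60, seed=3)


@pytest.fixture(scope="session")
def small_city_data(small_city):
    c = small_city
    names = list(c.covariates.columns)
    return BYMData(c.cases, c.populations, c.covariates.to_numpy(),
                   c.lattice, names)


@pytest.fixture(scope="session")
def small_fit(small_city_data):
    spec = BYMModelSpec(covariate_names=small_city_data.covariate_names)
    return fit(small_city_data, spec, seed=7, **FAST_FIT)
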