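import numpy as np
import pytest
from shapely.geometry import box

from faunarange.reconstruction import BorderGeometry
from faunarange.synthetic import SimulationConfig, generate_dataset


@pytest.fixture
def unit_border():
    """A 4 x 4 planar border for constructed geometry cases."""
    return BorderGeometry(box(0, 0, 4, 4))


@pytest.fixture(scope="session")
def small_sim_config():
    """A small but complete synthetic study system configuration."""
    return SimulationConfig(
        seed=11,
        n_species=10,
        holocene_sites=(10, 25),
        historical_sites=(6, 20),
        raster_cellsize_deg=0.5,
    )


@pytest.fixture(scope="session")
def synthetic_dataset(small_sim_config, tmp_path_factory):
    """Synthetic input files on disk plus their ground truth."""
    outdir = tmp_path_factory.mktemp("synth")
    truth = generate_dataset(small_sim_config, outdir)
    return outdir, truth


def monte_carlo_area(geom, n=200_000, seed=0):
    """Rejection-sampling area oracle for planar geometries."""
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = geom.bounds
    xs = rng.uniform(minx, maxx, n)
    ys = rng.uniform(miny, maxy, n)
    from shapely import contains_xy

    hits = contains_xy(geom, xs, ys).mean()
    return hits * (maxx - minx) * (maxy - miny)
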