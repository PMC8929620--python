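import numpy as np
import pytest

from lamap.raster import GridRaster
from lamap.synthetic import ScenarioConfig, SitePreference, make_scenario
from lamap.terrain import DerivativeStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid_factory():
    """Build a GridRaster from values with sensible georeferencing defaults."""

    def make(values, cell_size=15.0, origin_x=0.0, origin_y=None, **kw):
        values = np.asarray(values, dtype=float)
        if origin_y is None:
            origin_y = values.shape[0] * cell_size
        return GridRaster(
            values=values, origin_x=origin_x, origin_y=origin_y, cell_size=cell_size, **kw
        )

    return make


@pytest.fixture
def plane_factory(grid_factory):
    """DEM z = gx * x_east + gy * y_north + c on an n x n grid."""

    def make(n=9, gx=0.0, gy=0.0, c=100.0, cell_size=15.0):
        xs = (np.arange(n) + 0.5) * cell_size
        ys = (n - np.arange(n) - 0.5) * cell_size  # row 0 northernmost
        z = c + gx * xs[None, :] + gy * ys[:, None]
        return grid_factory(z, cell_size=cell_size)

    return make


def random_stack(rng, n=30, n_layers=3, cell_size=15.0) -> DerivativeStack:
    """Stack of independent noise layers (no terrain realism needed)."""
    layers = {}
    for i in range(n_layers):
        layers[f"v{i}"] = GridRaster(
            values=rng.normal(size=(n, n)),
            origin_x=0.0,
            origin_y=n * cell_size,
            cell_size=cell_size,
        )
    return DerivativeStack(layers=layers)


@pytest.fixture(scope="session")
def small_scenario():
    """One shared 64 x 64 scenario with preference on (cheap, reused read-only)."""
    cfg = ScenarioConfig(
        n_rows=64,
        n_cols=64,
        n_train=8,
        n_validation=16,
        preference=SitePreference(strength=3.0),
        viewshed_max_radius_m=1500.0,
        seed=11,
    )
    return make_scenario(cfg)
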