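import numpy as np
import pytest
import xarray as xr

from benthoshift.grids import DomainGrid
from benthoshift.synth import SeasonalCycle, generate_bathymetry


@pytest.fixture(scope="session")
def small_grid() -> DomainGrid:
    """A 20 x 24-cell grid with 8 depth levels — fast but non-trivial."""
    return DomainGrid(
        lon_min=-80.0,
        lon_max=-80.0 + 20 * 0.08,
        lat_min=1.46,
        lat_max=1.46 + 24 * 0.08,
        resolution=0.08,
        depth_levels=tuple(np.linspace(5.0, 1200.0, 8)),
    )


@pytest.fixture(scope="session")
def bathy(small_grid):
    return generate_bathymetry(small_grid, seed=11, noise_sd=20.0, land_cells=2)


@pytest.fixture()
def flat_season():
    return SeasonalCycle()


def raster(grid: DomainGrid, values) -> xr.DataArray:
    """2-D DataArray on a grid from an (n_lon, n_lat) array."""
    return xr.DataArray(
        np.asarray(values, dtype=float),
        dims=("lon", "lat"),
        coords={"lon": grid.lons, "lat": grid.lats},
    )


@pytest.fixture(scope="session")
def make_raster():
    return raster
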