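"""Working grid definition and spherical cell geometry.

Everything downstream (cubes, rasters, stacks, maps) lives on one
:class:`DomainGrid`: a regular lon/lat grid with cell-center registration,
an ordered set of depth-level centers (metres, positive down) and the
twelve calendar months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

EARTH_RADIUS_KM = 6371.0

MONTHS = tuple(range(1, 13))


def default_depth_levels(n_levels: int = 24, max_depth: float = 1200.0) -> tuple[float, ...]:
    """Level-center depths thickening quadratically with depth, as ocean
    reanalysis products do (fine near the surface, coarse at depth)."""
    k = np.arange(n_levels) + 0.5
    return tuple(np.round(max_depth * (k / n_levels) ** 2, 3))


@dataclass(frozen=True)
class DomainGrid:
    """Regular lon/lat grid with depth levels and months.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max : float
        Domain bounds in degrees; cells are ``resolution`` wide and
        registered on their centers.
    resolution : float
        Cell size in degrees (default 0.08).
    depth_levels : tuple of float
        Strictly increasing level-center depths in metres, positive down.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float = 0.08
    depth_levels: tuple[float, ...] = field(default_factory=default_depth_levels)
    months: tuple[int, ...] = MONTHS

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("empty domain extent")
        levels = np.asarray(self.depth_levels, dtype=float)
        if levels.size == 0 or np.any(np.diff(levels) <= 0):
            raise ValueError("depth_levels must be non-empty and strictly increasing")
        if np.any(levels < 0):
            raise ValueError("depth_levels are positive-down metres; negatives not allowed")

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def lons(self) -> np.ndarray:
        """Cell-center longitudes."""
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.resolution

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes."""
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.resolution

    @property
    def max_depth(self) -> float:
        return float(self.depth_levels[-1])

    def cell_area_km2(self) -> xr.DataArray:
        """Per-cell spherical area, A = R^2 * dlam * (sin(phi2) - sin(phi1)).

        Constant along longitude; returned broadcast to (lon, lat) so it
        aligns with any raster on this grid.
        """
        dlam = np.deg2rad(self.resolution)
        phi1 = np.deg2rad(self.lats - self.resolution / 2.0)
        phi2 = np.deg2rad(self.lats + self.resolution / 2.0)
        band = EARTH_RADIUS_KM**2 * dlam * (np.sin(phi2) - np.sin(phi1))
        areas = np.broadcast_to(band[np.newaxis, :], (self.n_lon, self.n_lat))
        return xr.DataArray(
            areas.copy(),
            dims=("lon", "lat"),
            coords={"lon": self.lons, "lat": self.lats},
            name="cell_area_km2",
            attrs={"units": "km2"},
        )

    def empty_raster(self, fill: float = np.nan, name: str | None = None) -> xr.DataArray:
        data = np.full((self.n_lon, self.n_lat), fill, dtype=float)
        return xr.DataArray(
            data, dims=("lon", "lat"), coords={"lon": self.lons, "lat": self.lats}, name=name
        )

    @classmethod
    def default_synthetic(cls) -> "DomainGrid":
        """50 x 60-cell coastal shelf domain at 0.08 degrees, 24 depth levels
        to 1200 m — small enough for full-pipeline runs in minutes."""
        return cls(
            lon_min=-80.0,
            lon_max=-80.0 + 50 * 0.08,
            lat_min=1.46,
            lat_max=1.46 + 60 * 0.08,
            resolution=0.08,
            depth_levels=default_depth_levels(24, 1200.0),
        )
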