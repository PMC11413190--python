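"""Seeded synthetic data: bathymetry, environmental cubes, coarse biased
"future" fields, and occurrences drawn from a known habitat model.

The generators emulate the statistical structure the pipeline assumes —
depth-stratified water-column variables with monomodal or bimodal seasonal
cycles over a coastal shelf, coarse future fields carrying a known additive
climate signal and a known model bias, and presence records sampled from a
known logistic suitability surface — so every downstream stage can be tested
against ground truth without any external download. All generators are pure
functions of (configuration, seed): reruns are byte-identical.

Conventions: depths are metres, positive down; land is encoded as missing
(NaN), never as depth zero.
"""

from __future__ import annotations

import warnings
from collections.abc import Callable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grids import DomainGrid

__all__ = [
    "SeasonalCycle",
    "TrueHabitatModel",
    "FutureFieldSpec",
    "generate_bathymetry",
    "generate_env_cube",
    "generate_future_fields",
    "sample_occurrences",
]


@dataclass(frozen=True)
class SeasonalCycle:
    """Monthly cycle with a declared number of peaks.

    kind: "flat", "monomodal" or "bimodal"; peaks lists the peak months
    (1..12), one for monomodal, two for bimodal. The cycle is a sum of
    wrapped Gaussian bumps (sigma in months), cyclic over the year.
    """

    kind: str = "flat"
    peaks: tuple[int, ...] = ()
    amplitude: float = 1.0
    sigma: float = 1.2

    def __post_init__(self) -> None:
        expected = {"flat": 0, "monomodal": 1, "bimodal": 2}
        if self.kind not in expected:
            raise ValueError(f"unknown season kind {self.kind!r}")
        if len(self.peaks) != expected[self.kind]:
            raise ValueError(f"{self.kind} cycle needs {expected[self.kind]} peak month(s)")
        if any(not 1 <= p <= 12 for p in self.peaks):
            raise ValueError("peak months must lie in 1..12")

    def values(self) -> np.ndarray:
        """The 12 monthly offsets."""
        months = np.arange(1, 13, dtype=float)
        out = np.zeros(12)
        for p in self.peaks:
            d = np.abs(months - p)
            d = np.minimum(d, 12 - d)  # cyclic distance
            out += self.amplitude * np.exp(-0.5 * (d / self.sigma) ** 2)
        return out


@dataclass(frozen=True)
class TrueHabitatModel:
    """Known logistic suitability: sigmoid(intercept + sum_i coef_i * x_i).

    The true range is where suitability >= threshold. This is the synthetic
    ground truth the ensemble classifier is asked to recover.
    """

    coefficients: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    threshold: float = 0.5

    def suitability(self, features: Mapping[str, np.ndarray]) -> np.ndarray:
        missing = set(self.coefficients) - set(features)
        if missing:
            raise KeyError(f"habitat model needs predictors {sorted(missing)}")
        z: np.ndarray | float = self.intercept
        for name, coef in self.coefficients.items():
            z = z + coef * np.asarray(features[name], dtype=float)
        z = np.asarray(z, dtype=float)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-z))

    def true_range(self, features: Mapping[str, np.ndarray]) -> np.ndarray:
        s = self.suitability(features)
        out = s >= self.threshold
        return np.where(np.isnan(s), False, out)


@dataclass(frozen=True)
class FutureFieldSpec:
    """Additive climate signal and model bias on a coarse grid.

    climate_delta and known_bias are either scalars or callables of
    (lon2d, lat2d); coarse_factor is the fine-to-coarse resolution ratio
    (1 degree vs 0.08 degrees is about 12).
    """

    climate_delta: float | Callable = 0.0
    known_bias: float | Callable = 0.0
    coarse_factor: int = 12

    def __post_init__(self) -> None:
        if self.coarse_factor < 1:
            raise ValueError("coarse_factor must be >= 1")


def _eval_field(spec: float | Callable, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lon2d, lat2d = np.meshgrid(lon, lat, indexing="ij")
    if callable(spec):
        return np.asarray(spec(lon2d, lat2d), dtype=float)
    return np.full(lon2d.shape, float(spec))


def generate_bathymetry(
    grid: DomainGrid,
    seed: int,
    noise_sd: float = 25.0,
    land_cells: int = 3,
    shelf_exponent: float = 1.6,
) -> xr.DataArray:
    """Synthetic shelf bathymetry: a coastline along the eastern edge,
    monotone deepening westward, seeded noise, land as NaN.

    Depths are clipped to [0, max depth level]; with ``noise_sd=0`` the
    result is the exact deterministic shelf profile.
    """
    rng = np.random.default_rng(seed)
    n_lon, n_lat = grid.n_lon, grid.n_lat
    if land_cells >= n_lon:
        raise ValueError("land strip covers the whole domain")
    # distance (in cells) from the coastline at the inner edge of the land strip
    i = np.arange(n_lon, dtype=float)
    coast = n_lon - land_cells - 1
    dist = np.clip((coast - i) / max(coast, 1), 0.0, 1.0)
    profile = grid.max_depth * dist**shelf_exponent
    depth = np.repeat(profile[:, np.newaxis], n_lat, axis=1)
    if noise_sd > 0:
        depth = depth + rng.normal(0.0, noise_sd, size=depth.shape)
    depth = np.clip(depth, 0.0, grid.max_depth)
    depth[n_lon - land_cells :, :] = np.nan  # land strip along the eastern edge
    return xr.DataArray(
        depth,
        dims=("lon", "lat"),
        coords={"lon": grid.lons, "lat": grid.lats},
        name="bathymetry",
        attrs={"units": "m", "positive": "down"},
    )


def generate_env_cube(
    grid: DomainGrid,
    profile: Callable[[np.ndarray], np.ndarray],
    season: SeasonalCycle,
    noise_sd: float,
    seed: int,
    gradient: float | Callable = 0.0,
    name: str = "variable",
    units: str = "",
) -> xr.DataArray:
    """4-D variable over (lon, lat, depth, month):

        value(x, y, z, m) = gradient(x, y) + profile(z) + season(m) + noise.

    ``gradient`` is a scalar or a callable of (lon2d, lat2d); ``profile`` maps
    depth-level centers to values; the cycle is cyclic in the month (December
    adjacent to January).
    """
    rng = np.random.default_rng(seed)
    levels = np.asarray(grid.depth_levels, dtype=float)
    g = _eval_field(gradient, grid.lons, grid.lats)  # (lon, lat)
    p = np.asarray(profile(levels), dtype=float)  # (depth,)
    s = season.values()  # (month,)
    values = (
        g[:, :, np.newaxis, np.newaxis]
        + p[np.newaxis, np.newaxis, :, np.newaxis]
        + s[np.newaxis, np.newaxis, np.newaxis, :]
    )
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    else:
        values = values + np.zeros_like(values)
    return xr.DataArray(
        values,
        dims=("lon", "lat", "depth", "month"),
        coords={
            "lon": grid.lons,
            "lat": grid.lats,
            "depth": levels,
            "month": np.arange(1, 13),
        },
        name=name,
        attrs={"units": units},
    )


def block_aggregate(da: xr.DataArray, factor: int) -> xr.DataArray:
    """Missing-aware block mean over (lon, lat) by an integer factor.

    Trailing rows/columns that do not fill a block are truncated with a
    warning, matching how regridding tools crop.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return da.copy()
    n_lon, n_lat = da.sizes["lon"], da.sizes["lat"]
    if n_lon % factor or n_lat % factor:
        warnings.warn(
            f"grid shape ({n_lon}, {n_lat}) not divisible by {factor}; "
            "truncating trailing cells",
            stacklevel=2,
        )
        da = da.isel(lon=slice(0, n_lon - n_lon % factor), lat=slice(0, n_lat - n_lat % factor))
    return da.coarsen(lon=factor, lat=factor).mean()


def generate_future_fields(
    current: xr.DataArray,
    spec: FutureFieldSpec,
    seed: int,
    model_noise_sd: float = 0.0,
) -> tuple[xr.DataArray, xr.DataArray]:
    """Coarse historical-model and future-model fields with known structure:

        hist_model  = block_mean(current) + known_bias  (+ optional noise)
        future_model = hist_model + climate_delta

    so a downstream delta correction should recover the current field plus
    the known climate signal, up to aggregation error.
    """
    rng = np.random.default_rng(seed)
    coarse = block_aggregate(current, spec.coarse_factor)
    bias = _eval_field(spec.known_bias, coarse["lon"].values, coarse["lat"].values)
    delta = _eval_field(spec.climate_delta, coarse["lon"].values, coarse["lat"].values)
    bias_da = xr.DataArray(bias, dims=("lon", "lat"), coords={"lon": coarse["lon"], "lat": coarse["lat"]})
    delta_da = bias_da.copy(data=delta)
    hist = coarse + bias_da
    if model_noise_sd > 0:
        noise = rng.normal(0.0, model_noise_sd, size=coarse.shape)
        hist = hist + xr.DataArray(noise, dims=coarse.dims, coords=coarse.coords)
    future = hist + delta_da
    hist = hist.transpose(*coarse.dims).rename(current.name)
    future = future.transpose(*coarse.dims).rename(current.name)
    return hist, future


def sample_occurrences(
    truth: TrueHabitatModel,
    stack: xr.Dataset,
    n: int,
    seed: int,
    species: str = "synthetic",
) -> pd.DataFrame:
    """Draw ``n`` presence records with probability proportional to the true
    suitability evaluated on the stack's annual-mean predictors.

    Records carry (lon, lat, depth, species, label=1); depth is read from the
    stack's BAT layer. Raises if the true suitability is zero everywhere.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    annual = stack.mean("month", skipna=True) if "month" in stack.dims else stack
    features = {name: annual[name].values for name in truth.coefficients}
    suit = truth.suitability(features)
    if "BAT" not in annual:
        raise KeyError("stack must contain a BAT layer to assign depths")
    bat = annual["BAT"].values
    ocean = np.isfinite(bat)
    for f in features.values():
        ocean &= np.isfinite(f)
    weights = np.where(ocean, suit, 0.0)
    total = weights.sum()
    if not total > 0:
        raise ValueError("true suitability is zero on every ocean cell")
    flat_p = (weights / total).ravel()
    idx = rng.choice(flat_p.size, size=n, p=flat_p)
    ii, jj = np.unravel_index(idx, weights.shape)
    lons = annual["lon"].values[ii]
    lats = annual["lat"].values[jj]
    depths = bat[ii, jj]
    return pd.DataFrame(
        {
            "lon": lons,
            "lat": lats,
            "depth": depths,
            "species": species,
            "label": np.ones(n, dtype=int),
            "set_id": np.zeros(n, dtype=int),
        }
    )
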