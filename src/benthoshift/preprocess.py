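"""Monthly climatologies, grid standardization, collinearity screening and
predictor-stack assembly."""

from __future__ import annotations

import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .grids import DomainGrid
from .scenarios import ScenarioSpec

STATIC_LAYERS = ("BAT", "BH")


def monthly_climatology(series: xr.DataArray) -> xr.DataArray:
    """Per-calendar-month, cell-wise, missing-aware mean.

    ``series`` has a ``time`` dimension with an integer ``month`` coordinate
    (1..12) attached. Every calendar month must be represented at least once;
    missing months raise with the offending month numbers listed.
    """
    if "time" not in series.dims:
        raise ValueError("series needs a 'time' dimension with a 'month' coordinate")
    months = np.asarray(series["month"].values)
    absent = sorted(set(range(1, 13)) - set(int(m) for m in months))
    if absent:
        raise ValueError(f"calendar months missing from series: {absent}")
    clim = series.groupby("month").mean("time", skipna=True)
    return clim.transpose(..., "month")


def resample_bilinear(raster: xr.DataArray, target: DomainGrid) -> xr.DataArray:
    """Bilinear interpolation onto the target grid's cell centers.

    Missing values propagate: any target cell whose interpolation stencil
    touches a missing source corner comes out missing. Raises if the extents
    are disjoint.
    """
    src_lon = raster["lon"].values
    src_lat = raster["lat"].values
    if target.lons.max() < src_lon.min() or target.lons.min() > src_lon.max():
        raise ValueError("source and target longitudes do not overlap")
    if target.lats.max() < src_lat.min() or target.lats.min() > src_lat.max():
        raise ValueError("source and target latitudes do not overlap")
    out = raster.interp(lon=target.lons, lat=target.lats, method="linear")
    return out


def pearson_matrix(layers: Mapping[str, xr.DataArray]) -> pd.DataFrame:
    """Pairwise Pearson correlations over jointly non-missing cells.

    A layer constant over the joint mask has undefined correlation; it is
    treated as uncorrelated (r = 0) with a warning.
    """
    names = list(layers)
    arrays = {n: np.asarray(layers[n].values, dtype=float).ravel() for n in names}
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x, y = arrays[a], arrays[b]
            m = np.isfinite(x) & np.isfinite(y)
            if m.sum() < 3:
                raise ValueError(f"fewer than 3 jointly non-missing cells for ({a}, {b})")
            xs, ys = x[m], y[m]
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                warnings.warn(
                    f"layer constant over joint mask in pair ({a}, {b}); treating r as 0",
                    stacklevel=2,
                )
                val = 0.0
            else:
                val = float(np.corrcoef(xs, ys)[0, 1])
            r.loc[a, b] = r.loc[b, a] = val
    return r


def collinearity_filter(
    layers: Mapping[str, xr.DataArray], threshold: float = 0.70
) -> tuple[list[str], pd.DataFrame]:
    """Drop predictors until no retained pair has |Pearson r| > threshold.

    Greedy elimination: repeatedly drop the variable with the highest mean
    absolute correlation to the remaining ones, ties broken by lexicographic
    name. Pairs with |r| exactly at the threshold are retained. Returns the
    retained names (input order) and the full correlation matrix.
    """
    if len(layers) < 2:
        raise ValueError("need at least two candidate layers")
    corr = pearson_matrix(layers)
    kept = list(layers)
    while True:
        sub = corr.loc[kept, kept].abs()
        mask = np.triu(np.ones(sub.shape, dtype=bool), k=1)
        offending = sub.where(mask) > threshold
        if not offending.any().any():
            break
        means = sub.where(~np.eye(len(kept), dtype=bool)).mean()
        worst = means.loc[sorted(kept)].idxmax()  # lexicographic tie-break
        # only variables involved in an offending pair are candidates for removal
        involved = set()
        rows, cols = np.where(offending.values)
        for i, j in zip(rows, cols):
            involved.add(kept[i])
            involved.add(kept[j])
        cand = means[list(involved)]
        top = cand.max()
        worst = sorted(cand[cand == top].index)[0]
        kept.remove(worst)
        if len(kept) < 2:
            break
    retained = [n for n in layers if n in kept]
    return retained, corr


def assemble_stack(
    bottom: Mapping[str, xr.DataArray],
    surface: Mapping[str, xr.DataArray],
    static: Mapping[str, xr.DataArray],
    scenario: ScenarioSpec,
) -> xr.Dataset:
    """Co-registered named predictor stack for one scenario.

    ``bottom`` and ``surface`` layers carry a month dimension; ``static``
    layers (BAT, BH) do not and are injected unchanged into every scenario.
    Raises on duplicate or missing-required layer names.
    """
    all_names = list(bottom) + list(surface) + list(static)
    dupes = {n for n in all_names if all_names.count(n) > 1}
    if dupes:
        raise ValueError(f"layer name collision: {sorted(dupes)}")
    if "BAT" not in static:
        raise ValueError("static layers must include BAT")
    data = {}
    for name, da in {**bottom, **surface}.items():
        if "month" not in da.dims:
            raise ValueError(f"dynamic layer {name!r} lacks a month dimension")
        data[name] = da.transpose("lon", "lat", "month")
    for name, da in static.items():
        data[name] = da.transpose("lon", "lat")
    ds = xr.Dataset(data)
    ds.attrs["decade"] = scenario.decade
    ds.attrs["ssp"] = "" if scenario.ssp is None else str(scenario.ssp)
    ds.attrs["scenario"] = scenario.name
    return ds


def annual_mean_stack(stack: xr.Dataset) -> xr.Dataset:
    """Collapse the month dimension by a missing-aware mean; static layers
    pass through unchanged."""
    out = stack.mean("month", skipna=True) if "month" in stack.dims else stack
    out.attrs = dict(stack.attrs)
    return out
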