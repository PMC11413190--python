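"""Bathymetric projection: collapse a 4-D water-column variable onto the
seafloor, producing 2-D monthly bottom layers.

For each horizontal cell the bathymetry raster gives the seabed depth; the
projection picks, per month, the value of the water-column variable at the
depth level coinciding with the seafloor. The default policy is
"deepest-valid": the deepest level whose center depth lies at or above the
seabed and whose value is non-missing. It never fabricates values below the
data column. An "interpolate" policy linearly blends the two levels
bracketing the seabed when both carry data, falling back to deepest-valid
otherwise. Cells shallower than the first level center use the first level
(surface waters are the best proxy at zero-depth cells); columns with no
valid level at or above the seabed fall back to the deepest non-missing
level and are flagged.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

POLICIES = ("deepest-valid", "interpolate")


def project_to_bottom(
    cube: xr.DataArray,
    bathymetry: xr.DataArray,
    policy: str = "deepest-valid",
) -> xr.Dataset:
    """Project an (lon, lat, depth, month) cube to the seafloor.

    Returns a Dataset with:

    - ``value`` (lon, lat, month): the bottom-coincident layer;
    - ``level_index`` (lon, lat, month): provenance — the selected depth-level
      index, -1 where the output is missing;
    - ``fallback`` (lon, lat, month): True where no valid level existed at or
      above the seabed and the deepest valid level was used instead.

    Land cells (missing bathymetry) and all-missing columns yield missing
    output.
    """
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")
    if not np.array_equal(cube["lon"].values, bathymetry["lon"].values) or not np.array_equal(
        cube["lat"].values, bathymetry["lat"].values
    ):
        raise ValueError("cube and bathymetry must share the horizontal grid")

    cube = cube.transpose("lon", "lat", "depth", "month")
    v = cube.values  # (nx, ny, nz, nm)
    levels = cube["depth"].values
    b = bathymetry.values  # (nx, ny)
    nx, ny, nz, nm = v.shape

    ocean = np.isfinite(b)
    # deepest level whose center is at or above the seabed; shallower-than-first
    # cells use level 0
    target = np.searchsorted(levels, np.where(ocean, b, 0.0), side="right") - 1
    target = np.clip(target, 0, nz - 1)  # (nx, ny)

    valid = np.isfinite(v)  # (nx, ny, nz, nm)
    k = np.arange(nz)[np.newaxis, np.newaxis, :, np.newaxis]
    at_or_above = k <= target[:, :, np.newaxis, np.newaxis]

    chosen = np.where(valid & at_or_above, k, -1).max(axis=2)  # (nx, ny, nm)
    deepest_valid = np.where(valid, k, -1).max(axis=2)
    fallback = (chosen < 0) & (deepest_valid >= 0)
    chosen = np.where(chosen < 0, deepest_valid, chosen)
    chosen = np.where(ocean[:, :, np.newaxis], chosen, -1)

    gather = np.clip(chosen, 0, nz - 1)
    out = np.take_along_axis(v, gather[:, :, np.newaxis, :], axis=2)[:, :, 0, :]
    out = np.where(chosen >= 0, out, np.nan)

    if policy == "interpolate":
        # blend with the level below the seabed where that level carries data
        below = np.minimum(gather + 1, nz - 1)
        v_below = np.take_along_axis(v, below[:, :, np.newaxis, :], axis=2)[:, :, 0, :]
        z_lo = levels[gather]
        z_hi = levels[below]
        can = (
            (chosen >= 0)
            & ~fallback
            & (chosen == target[:, :, np.newaxis])
            & (below > gather)
            & np.isfinite(v_below)
            & (b[:, :, np.newaxis] > z_lo)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.clip((b[:, :, np.newaxis] - z_lo) / (z_hi - z_lo), 0.0, 1.0)
        out = np.where(can, (1 - w) * out + w * v_below, out)

    coords = {"lon": cube["lon"], "lat": cube["lat"], "month": cube["month"]}
    return xr.Dataset(
        {
            "value": xr.DataArray(out, dims=("lon", "lat", "month"), coords=coords),
            "level_index": xr.DataArray(
                chosen.astype(np.int32), dims=("lon", "lat", "month"), coords=coords
            ),
            "fallback": xr.DataArray(
                (fallback & ocean[:, :, np.newaxis]), dims=("lon", "lat", "month"), coords=coords
            ),
        },
        attrs={"policy": policy},
    )
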