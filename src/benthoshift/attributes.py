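"""Spatiotemporal attributes of suitability maps and their change versus
the current decade: area, depth range, spatial aggregation, percentage
suitability change, gained/lost areas, and seasonality.

Conventions baked in here:

- Per-cell area uses the spherical formula A = R^2 * dlam * (sin phi2 -
  sin phi1), R = 6371 km, so cell areas shrink correctly with latitude.
- The aggregation index AI = 100 * e / max_e, where e counts rook
  (edge-sharing) like-adjacencies among presence cells, each shared edge
  once, and max_e is the largest-integer-square maximum for n cells:
  with m = floor(sqrt(n)) and r = n - m^2, max_e = 2m(m-1) when r = 0,
  2m(m-1) + 2r - 1 when 0 < r <= m, and 2m(m-1) + 2r - 2 when r > m.
  AI runs from 0 (complete fragmentation) to 100 (complete connectivity)
  and is undefined for n <= 1.
- Suitability change compares CP(o) cell-wise: a change is positive when
  the future value exceeds the current by more than 0.10 on the [0, 1]
  scale (10 percentage points), negative below -0.10, no-change within the
  band. A relative reading (10% of the current value) sits behind
  ``mode="relative"``. Percentages are evaluated over the union of the
  current and future presence footprints.
- Seasonality departure: Kendall tau-b between the current and future
  12-month series of an attribute; a departure is flagged when the
  correlation is not significant at alpha (so, taken literally, a strongly
  negative but significant tau still counts as "no departure" — see the
  methods note).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .grids import DomainGrid

CHANGE_CODES = {"negative": -1, "no-change": 0, "positive": 1}
TRANSITION_CODES = {"stable-absent": 0, "stable-present": 1, "gained": 2, "lost": 3}


def compute_area(binary: xr.DataArray, grid: DomainGrid) -> float:
    """Total area (km^2) of presence cells; empty maps give 0."""
    pres = binary.transpose("lon", "lat").values == 1.0
    if not pres.any():
        return 0.0
    areas = grid.cell_area_km2().values
    return float(areas[pres].sum())


def depth_stats(binary: xr.DataArray, bathymetry: xr.DataArray) -> tuple[float, float, float]:
    """(min, max, mean) bathymetry depth (m) over presence cells.

    An empty map has no depth distribution; returns NaNs with a warning
    (the blank-row case).
    """
    pres = binary.transpose("lon", "lat").values == 1.0
    depths = bathymetry.transpose("lon", "lat").values
    sel = depths[pres & np.isfinite(depths)]
    if sel.size == 0:
        warnings.warn("empty binary map: depth range undefined", stacklevel=2)
        return (np.nan, np.nan, np.nan)
    return (float(sel.min()), float(sel.max()), float(sel.mean()))


def max_like_adjacencies(n: int) -> int:
    """Largest possible number of rook like-adjacencies for n cells (the
    largest-integer-square arrangement)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    m = int(np.floor(np.sqrt(n)))
    r = n - m * m
    if r == 0:
        return 2 * m * (m - 1)
    if r <= m:
        return 2 * m * (m - 1) + 2 * r - 1
    return 2 * m * (m - 1) + 2 * r - 2


def count_like_adjacencies(mask: np.ndarray) -> int:
    """Shared edges between presence cells, each counted once (rook moves)."""
    mask = np.asarray(mask, dtype=bool)
    horiz = np.sum(mask[:-1, :] & mask[1:, :])
    vert = np.sum(mask[:, :-1] & mask[:, 1:])
    return int(horiz + vert)


def aggregation_index(binary: xr.DataArray | np.ndarray) -> tuple[float, int, int]:
    """(AI, e, max_e): AI = 100 * e / max_e in [0, 100]; NaN (with warning)
    when fewer than two presence cells exist."""
    if isinstance(binary, xr.DataArray):
        mask = binary.transpose("lon", "lat").values == 1.0
    else:
        mask = np.asarray(binary) == 1.0
    n = int(mask.sum())
    e = count_like_adjacencies(mask)
    if n <= 1:
        warnings.warn("aggregation index undefined for n <= 1 presence cells", stacklevel=2)
        return (np.nan, e, 0)
    max_e = max_like_adjacencies(n)
    return (100.0 * e / max_e, e, max_e)


def suitability_change(
    current: xr.DataArray,
    future: xr.DataArray,
    band: float = 0.10,
    mode: str = "absolute",
    presence_threshold: float = 0.75,
) -> tuple[xr.DataArray, dict[str, float]]:
    """Classify cell-wise CP(o) change and summarize class percentages.

    Returns a categorical map coded {-1 negative, 0 no-change, +1 positive,
    NaN unevaluated} and percentages over the evaluated cells (the union of
    current and future presence footprints at ``presence_threshold``); the
    percentages sum to 100 where any cell is evaluated.
    """
    if current.sizes != future.sizes:
        raise ValueError("current and future maps are not co-registered")
    cur = current.transpose("lon", "lat").values
    fut = future.transpose("lon", "lat").values
    delta = fut - cur
    if mode == "relative":
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(cur != 0, delta / np.abs(cur), np.inf * np.sign(delta))
    elif mode != "absolute":
        raise ValueError("mode must be 'absolute' or 'relative'")
    footprint = (cur >= presence_threshold) | (fut >= presence_threshold)
    footprint &= np.isfinite(cur) & np.isfinite(fut)
    codes = np.where(delta > band, 1.0, np.where(delta < -band, -1.0, 0.0))
    codes = np.where(footprint, codes, np.nan)
    n_eval = footprint.sum()
    if n_eval:
        pct = {
            "positive": 100.0 * np.sum(codes == 1) / n_eval,
            "negative": 100.0 * np.sum(codes == -1) / n_eval,
            "no-change": 100.0 * np.sum(codes == 0) / n_eval,
        }
    else:
        pct = {"positive": np.nan, "negative": np.nan, "no-change": np.nan}
    da = current.copy(data=codes)
    da.name = "suitability_change"
    da.attrs = {"codes": "-1 negative, 0 no-change, +1 positive", "band": band, "mode": mode}
    return da, pct


def gain_loss(
    current: xr.DataArray, future: xr.DataArray, grid: DomainGrid
) -> tuple[xr.DataArray, float, float]:
    """Transition map and gained/lost areas between two binary maps.

    Codes: 0 stable-absent, 1 stable-present, 2 gained (0 -> 1),
    3 lost (1 -> 0); NaN where either map is missing. Returns
    (map, gained_km2, lost_km2). Conservation holds exactly:
    gained - lost = future area - current area.
    """
    if current.sizes != future.sizes:
        raise ValueError("current and future maps are not co-registered")
    cur = current.transpose("lon", "lat").values
    fut = future.transpose("lon", "lat").values
    valid = np.isfinite(cur) & np.isfinite(fut)
    codes = np.full(cur.shape, np.nan)
    codes[valid & (cur == 0) & (fut == 0)] = TRANSITION_CODES["stable-absent"]
    codes[valid & (cur == 1) & (fut == 1)] = TRANSITION_CODES["stable-present"]
    codes[valid & (cur == 0) & (fut == 1)] = TRANSITION_CODES["gained"]
    codes[valid & (cur == 1) & (fut == 0)] = TRANSITION_CODES["lost"]
    areas = grid.cell_area_km2().values
    gained = float(areas[codes == TRANSITION_CODES["gained"]].sum())
    lost = float(areas[codes == TRANSITION_CODES["lost"]].sum())
    da = current.copy(data=codes)
    da.name = "transition"
    da.attrs = {"codes": "0 stable-absent, 1 stable-present, 2 gained, 3 lost"}
    return da, gained, lost


def seasonality_test(
    current_series: np.ndarray, future_series: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Kendall tau-b between two 12-month attribute series.

    Returns (tau, p, departure) with departure = (p >= alpha): the future
    seasonality departs from the current one when the rank correlation is
    not significant. Constant series leave tau undefined; that counts as a
    departure, with a warning. Months with no predicted distribution should
    enter as zeros, keeping the series length 12.
    """
    cur = np.asarray(current_series, dtype=float)
    fut = np.asarray(future_series, dtype=float)
    if cur.shape != (12,) or fut.shape != (12,):
        raise ValueError("both series must have length 12")
    if np.ptp(cur) == 0 or np.ptp(fut) == 0:
        warnings.warn("constant attribute series: Kendall tau undefined", stacklevel=2)
        return (np.nan, np.nan, True)
    res = stats.kendalltau(cur, fut, variant="b", method="auto")
    tau, p = float(res.statistic), float(res.pvalue)
    return (tau, p, bool(p >= alpha))


def attribute_record(
    binary: xr.DataArray,
    bathymetry: xr.DataArray,
    grid: DomainGrid,
) -> dict[str, float]:
    """The per-map attributes: area, depth min/max/mean, aggregation index."""
    area = compute_area(binary, grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dmin, dmax, dmean = depth_stats(binary, bathymetry)
        ai, e, max_e = aggregation_index(binary)
    return {
        "area_km2": area,
        "depth_min_m": dmin,
        "depth_max_m": dmax,
        "depth_mean_m": dmean,
        "aggregation_index": ai,
        "like_adjacencies": e,
        "max_like_adjacencies": max_e,
    }


def _change_flag(current: float, future: float, tol_pct: float = 1.0) -> tuple[str, float]:
    """Increase/stable/decrease flag and relative change (%) vs. current."""
    if not np.isfinite(current) or not np.isfinite(future):
        return ("undefined", np.nan)
    if current == 0:
        if future == 0:
            return ("stable", 0.0)
        return ("increase", np.inf)
    rel = 100.0 * (future - current) / current
    if rel > tol_pct:
        return ("increase", rel)
    if rel < -tol_pct:
        return ("decrease", rel)
    return ("stable", rel)


def build_attribute_table(
    suitability: dict[tuple[str, str, int], xr.DataArray],
    binary: dict[tuple[str, str, int], xr.DataArray],
    bathymetry: xr.DataArray,
    grid: DomainGrid,
    change_band: float = 0.10,
    presence_threshold: float = 0.75,
) -> pd.DataFrame:
    """One row per (species, scenario, month) with the six attributes and
    the comparison against the current decade.

    ``suitability`` and ``binary`` map (species, scenario_name, month) keys
    to maps; every species needs a "current" scenario. Future rows carry
    suitability-change percentages, gained/lost areas, and
    increase/stable/decrease flags for area (relative change beyond +-1%).
    Scenario-months whose maps are entirely below the presence threshold
    yield blank (NaN) depth/AI fields rather than errors.
    """
    rows = []
    keys = sorted(binary)
    for species, scenario, month in keys:
        bmap = binary[(species, scenario, month)]
        rec = attribute_record(bmap, bathymetry, grid)
        row = {"species": species, "scenario": scenario, "month": month, **rec}
        if scenario != "current":
            cur_key = (species, "current", month)
            if cur_key in binary:
                cur_bin = binary[cur_key]
                _, gained, lost = gain_loss(cur_bin, bmap, grid)
                row["gained_km2"] = gained
                row["lost_km2"] = lost
                flag, rel = _change_flag(
                    compute_area(cur_bin, grid), rec["area_km2"]
                )
                row["area_change_flag"] = flag
                row["area_change_pct"] = rel
                suit_key = (species, scenario, month)
                if suit_key in suitability and cur_key in suitability:
                    _, pct = suitability_change(
                        suitability[cur_key],
                        suitability[suit_key],
                        band=change_band,
                        presence_threshold=presence_threshold,
                    )
                    row["suit_positive_pct"] = pct["positive"]
                    row["suit_negative_pct"] = pct["negative"]
                    row["suit_nochange_pct"] = pct["no-change"]
        rows.append(row)
    return pd.DataFrame(rows)


def seasonality_table(
    attributes: pd.DataFrame,
    value_col: str = "area_km2",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kendall seasonality comparison of every future scenario against the
    current decade, per species, on one attribute's 12-month series.

    Months absent from a scenario contribute 0 (no habitat that month).
    """
    rows = []
    for species, sdf in attributes.groupby("species"):
        cur = np.zeros(12)
        cdf = sdf[sdf["scenario"] == "current"]
        cur[cdf["month"].values.astype(int) - 1] = np.nan_to_num(cdf[value_col].values)
        for scenario, fdf in sdf[sdf["scenario"] != "current"].groupby("scenario"):
            fut = np.zeros(12)
            fut[fdf["month"].values.astype(int) - 1] = np.nan_to_num(fdf[value_col].values)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tau, p, departure = seasonality_test(cur, fut, alpha=alpha)
            rows.append(
                {
                    "species": species,
                    "scenario": scenario,
                    "attribute": value_col,
                    "tau": tau,
                    "p_value": p,
                    "departure": departure,
                }
            )
    return pd.DataFrame(rows)
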