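"""Areas, depth ranges, aggregation index (with a brute-force adjacency
oracle), suitability change, gain/loss conservation and Kendall
seasonality."""

import itertools
import math
import warnings

import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from benthoshift.attributes import (
    _change_flag,
    aggregation_index,
    build_attribute_table,
    compute_area,
    count_like_adjacencies,
    depth_stats,
    gain_loss,
    max_like_adjacencies,
    seasonality_test,
    suitability_change,
)
from benthoshift.grids import DomainGrid
from benthoshift.sdm import binarize


def _binary(grid, mask):
    return xr.DataArray(
        np.asarray(mask, dtype=float),
        dims=("lon", "lat"),
        coords={"lon": grid.lons, "lat": grid.lats},
    )


def brute_force_adjacencies(mask):
    """O(n^2) pairwise rook-adjacency count — the independent oracle."""
    cells = list(zip(*np.nonzero(mask)))
    e = 0
    for a, b in itertools.combinations(cells, 2):
        if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1:
            e += 1
    return e


class TestArea:
    def test_empty_map_is_zero(self, small_grid):
        m = _binary(small_grid, np.zeros((small_grid.n_lon, small_grid.n_lat)))
        assert compute_area(m, small_grid) == 0.0

    def test_single_equator_cell_matches_spherical_arithmetic(self):
        grid = DomainGrid(
            lon_min=0.0, lon_max=0.8, lat_min=-0.4, lat_max=0.4,
            resolution=0.08, depth_levels=(10.0,),
        )
        mask = np.zeros((grid.n_lon, grid.n_lat))
        j = grid.n_lat // 2
        mask[0, j] = 1  # near-equator cell
        area = compute_area(_binary(grid, mask), grid)
        R = 6371.0
        dlam = math.radians(0.08)
        lat_c = grid.lats[j]
        expected = R * R * dlam * (
            math.sin(math.radians(lat_c + 0.04)) - math.sin(math.radians(lat_c - 0.04))
        )
        assert area == pytest.approx(expected, rel=1e-9)
        assert area == pytest.approx(79.13, abs=0.5)

    def test_additive_along_a_latitude_band(self, small_grid):
        mask = np.zeros((small_grid.n_lon, small_grid.n_lat))
        mask[3, 4] = 1
        one = compute_area(_binary(small_grid, mask), small_grid)
        mask[4:7, 4] = 1
        four = compute_area(_binary(small_grid, mask), small_grid)
        assert four == pytest.approx(4 * one, rel=1e-12)


class TestDepthStats:
    def test_hand_example(self, small_grid, make_raster):
        depths = np.full((small_grid.n_lon, small_grid.n_lat), np.nan)
        depths[0, 0], depths[0, 1], depths[0, 2] = 5.0, 10.0, 30.0
        mask = np.zeros_like(depths)
        mask[0, :3] = 1
        got = depth_stats(_binary(small_grid, mask), make_raster(small_grid, depths))
        assert got == (5.0, 30.0, 15.0)

    def test_single_cell_collapses(self, small_grid, bathy):
        mask = np.zeros((small_grid.n_lon, small_grid.n_lat))
        mask[1, 1] = 1
        mn, mx, mean = depth_stats(_binary(small_grid, mask), bathy)
        assert mn == mx == mean

    def test_empty_map_warns_nan(self, small_grid, bathy):
        mask = np.zeros((small_grid.n_lon, small_grid.n_lat))
        with pytest.warns(UserWarning, match="empty"):
            got = depth_stats(_binary(small_grid, mask), bathy)
        assert all(np.isnan(g) for g in got)

    def test_ordering_invariant_on_random_maps(self, small_grid, bathy):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mask = (rng.random((small_grid.n_lon, small_grid.n_lat)) < 0.3).astype(float)
            if not mask.any():
                continue
            mn, mx, mean = depth_stats(_binary(small_grid, mask), bathy)
            assert mn <= mean <= mx


class TestAggregationIndex:
    def test_solid_2x2_block_fully_aggregated(self, small_grid):
        mask = np.zeros((small_grid.n_lon, small_grid.n_lat))
        mask[0:2, 0:2] = 1
        ai, e, max_e = aggregation_index(_binary(small_grid, mask))
        assert (e, max_e) == (4, 4)
        assert ai == 100.0

    def test_diagonal_scatter_fully_fragmented(self, small_grid):
        mask = np.zeros((small_grid.n_lon, small_grid.n_lat))
        for k in range(4):
            mask[2 * k, 2 * k] = 1
        ai, e, _ = aggregation_index(_binary(small_grid, mask))
        assert e == 0
        assert ai == 0.0

    def test_undefined_below_two_cells(self, small_grid):
        mask = np.zeros((small_grid.n_lon, small_grid.n_lat))
        mask[0, 0] = 1
        with pytest.warns(UserWarning, match="undefined"):
            ai, _, _ = aggregation_index(_binary(small_grid, mask))
        assert np.isnan(ai)

    def test_exhaustive_4x4_maps_against_oracle(self):
        # every mask on a 4x4 grid with 2..9 presence cells
        for bits in range(1 << 16):
            mask = np.array([(bits >> k) & 1 for k in range(16)]).reshape(4, 4)
            n = mask.sum()
            if not 2 <= n <= 9:
                continue
            e_fast = count_like_adjacencies(mask)
            e_slow = brute_force_adjacencies(mask)
            assert e_fast == e_slow
            ai = 100.0 * e_fast / max_like_adjacencies(n)
            assert 0.0 <= ai <= 100.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**25 - 1))
    def test_random_5x5_maps_match_oracle(self, bits):
        mask = np.array([(bits >> k) & 1 for k in range(25)]).reshape(5, 5)
        n = int(mask.sum())
        if n <= 1:
            return
        grid = DomainGrid(0.0, 0.4, 0.0, 0.4, 0.08, (10.0,))
        ai, e, max_e = aggregation_index(_binary(grid, mask))
        assert e == brute_force_adjacencies(mask)
        assert ai == pytest.approx(100.0 * e / max_e)
        assert ai <= 100.0

    def test_largest_square_formula_matches_constructions(self):
        # n = m^2 solid squares realize the maximum exactly
        for m in range(2, 6):
            mask = np.zeros((m, m))
            mask[:, :] = 1
            assert count_like_adjacencies(mask) == max_like_adjacencies(m * m) == 2 * m * (m - 1)


class TestSuitabilityChange:
    def _pair(self, small_grid, cur_val, fut_val):
        shape = (small_grid.n_lon, small_grid.n_lat)
        cur = _binary(small_grid, np.full(shape, cur_val))
        fut = _binary(small_grid, np.full(shape, fut_val))
        return cur, fut

    @pytest.mark.parametrize(
        "cur,fut,expected",
        [(0.80, 0.95, 1.0), (0.80, 0.72, 0.0), (0.80, 0.50, -1.0)],
    )
    def test_band_rule(self, small_grid, cur, fut, expected):
        c, f = self._pair(small_grid, cur, fut)
        codes, pct = suitability_change(c, f)
        assert np.all(codes.values[np.isfinite(codes.values)] == expected)

    def test_percentages_sum_to_100(self, small_grid):
        rng = np.random.default_rng(0)
        shape = (small_grid.n_lon, small_grid.n_lat)
        cur = _binary(small_grid, rng.random(shape))
        fut = _binary(small_grid, rng.random(shape))
        _, pct = suitability_change(cur, fut)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_evaluation_domain_is_presence_union(self, small_grid):
        shape = (small_grid.n_lon, small_grid.n_lat)
        cur = np.full(shape, 0.1)
        fut = np.full(shape, 0.1)
        cur[0, 0] = 0.9  # only this cell enters the footprint
        codes, pct = suitability_change(_binary(small_grid, cur), _binary(small_grid, fut))
        assert np.isfinite(codes.values).sum() == 1
        assert pct["negative"] == 100.0


class TestGainLoss:
    def test_identical_maps_no_change(self, small_grid):
        rng = np.random.default_rng(1)
        mask = (rng.random((small_grid.n_lon, small_grid.n_lat)) < 0.4).astype(float)
        m = _binary(small_grid, mask)
        _, gained, lost = gain_loss(m, m, small_grid)
        assert gained == lost == 0.0

    def test_empty_to_full_everything_gained(self, small_grid):
        shape = (small_grid.n_lon, small_grid.n_lat)
        cur = _binary(small_grid, np.zeros(shape))
        fut = _binary(small_grid, np.ones(shape))
        codes, gained, lost = gain_loss(cur, fut, small_grid)
        assert lost == 0.0
        assert gained == pytest.approx(compute_area(fut, small_grid))
        assert np.all(codes.values == 2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_area_conservation_on_random_pairs(self, small_grid, seed):
        rng = np.random.default_rng(seed)
        shape = (small_grid.n_lon, small_grid.n_lat)
        cur = _binary(small_grid, (rng.random(shape) < 0.4).astype(float))
        fut = _binary(small_grid, (rng.random(shape) < 0.4).astype(float))
        _, gained, lost = gain_loss(cur, fut, small_grid)
        diff = compute_area(fut, small_grid) - compute_area(cur, small_grid)
        assert gained - lost == pytest.approx(diff, abs=1e-7)


class TestSeasonality:
    def test_identical_distinct_series_track(self):
        cur = np.arange(1.0, 13.0)
        tau, p, departure = seasonality_test(cur, cur.copy())
        assert tau == pytest.approx(1.0)
        assert p < 0.05
        assert departure is False

    def test_reversed_series_still_significant(self):
        # the literal rule: a significant negative correlation is not a
        # "departure" even though the seasonality is inverted
        cur = np.arange(1.0, 13.0)
        tau, p, departure = seasonality_test(cur, cur[::-1].copy())
        assert tau == pytest.approx(-1.0)
        assert p < 0.05
        assert departure is False

    def test_seeded_permutation_departs(self):
        cur = np.arange(1.0, 13.0)
        fut = np.random.default_rng(1).permutation(cur)
        tau, p, departure = seasonality_test(cur, fut)
        assert p >= 0.05
        assert departure is True

    def test_constant_series_warns_and_departs(self):
        cur = np.arange(1.0, 13.0)
        with pytest.warns(UserWarning, match="constant"):
            tau, p, departure = seasonality_test(cur, np.zeros(12))
        assert np.isnan(tau)
        assert departure is True

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            seasonality_test(np.arange(11.0), np.arange(11.0))


class TestThresholdMonotonicity:
    def test_raising_threshold_never_increases_area(self, small_grid):
        rng = np.random.default_rng(2)
        suit = _binary(small_grid, rng.random((small_grid.n_lon, small_grid.n_lat)))
        areas = [
            compute_area(binarize(suit, t), small_grid) for t in (0.25, 0.5, 0.75, 0.9)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestAttributeTable:
    def test_percent_change_arithmetic_anchor(self):
        # a 100 -> 392 km^2 area change is a +292% rise
        flag, rel = _change_flag(100.0, 392.0)
        assert flag == "increase"
        assert rel == pytest.approx(292.0)

    def test_stable_flag_within_one_percent(self):
        flag, rel = _change_flag(100.0, 100.5)
        assert flag == "stable"

    def test_table_rows_and_depth_ordering(self, small_grid, bathy):
        rng = np.random.default_rng(3)
        shape = (small_grid.n_lon, small_grid.n_lat)
        suit, binm = {}, {}
        for scen in ("current", "2030_2.6"):
            for m in range(1, 13):
                s = _binary(small_grid, rng.random(shape))
                suit[("sp", scen, m)] = s
                binm[("sp", scen, m)] = binarize(s, 0.6)
        df = build_attribute_table(suit, binm, bathy, small_grid, presence_threshold=0.6)
        assert len(df) == 24
        ok = df.dropna(subset=["depth_min_m"])
        assert (ok["depth_min_m"] <= ok["depth_mean_m"]).all()
        assert (ok["depth_mean_m"] <= ok["depth_max_m"]).all()
        fut = df[df["scenario"] != "current"]
        assert {"gained_km2", "lost_km2", "suit_positive_pct"} <= set(fut.columns)

    def test_blank_months_produce_nan_rows_not_errors(self, small_grid, bathy):
        shape = (small_grid.n_lon, small_grid.n_lat)
        suit, binm = {}, {}
        for scen in ("current", "2030_2.6"):
            for m in range(1, 13):
                s = _binary(small_grid, np.full(shape, 0.1))
                suit[("sp", scen, m)] = s
                binm[("sp", scen, m)] = binarize(s, 0.75)
        df = build_attribute_table(suit, binm, bathy, small_grid)
        assert len(df) == 24
        assert (df["area_km2"] == 0).all()
        assert df["depth_mean_m"].isna().all()
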