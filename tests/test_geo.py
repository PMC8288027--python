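import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, box

from vectorscape import geo
from vectorscape.raster import GridSpec, RasterStack


def brute_force_cells(a, b, grid: GridSpec) -> set[tuple[int, int]]:
    """Independent oracle: every cell whose box intersects the segment."""
    seg = LineString([a, b])
    out = set()
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            x0 = grid.x_origin + c * grid.cell_size
            y1 = grid.y_origin - r * grid.cell_size
            cell = box(x0, y1 - grid.cell_size, x0 + grid.cell_size, y1)
            if cell.intersects(seg):
                out.add((r, c))
    return out


class TestRasterline:
    def test_degenerate_same_cell(self, plain_grid):
        cells = geo.rasterline_cells((3.2, 10.4), (3.7, 10.1), plain_grid)
        assert cells == [(9, 3)]

    def test_axis_aligned_row(self, plain_grid):
        cells = geo.rasterline_cells((0.5, 10.5), (9.5, 10.5), plain_grid)
        assert cells == [(9, c) for c in range(10)]

    def test_random_pairs_match_brute_force_and_are_valid_paths(self):
        grid = GridSpec(n_rows=12, n_cols=15, x_origin=0, y_origin=12.0)
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = (rng.uniform(0, 15), rng.uniform(0, 12))
            b = (rng.uniform(0, 15), rng.uniform(0, 12))
            cells = geo.rasterline_cells(a, b, grid)
            assert set(cells) == brute_force_cells(a, b, grid)
            assert len(set(cells)) == len(cells), "no cell repeated"
            assert cells[0] == grid.cell_of(*a)
            assert cells[-1] == grid.cell_of(*b)
            for (r1, c1), (r2, c2) in zip(cells, cells[1:]):
                assert max(abs(r1 - r2), abs(c1 - c2)) == 1, "8-neighbor chain"
            assert geo.rasterline_cells(b, a, grid) == list(reversed(cells))

    def test_endpoint_outside_rejected(self, plain_grid):
        with pytest.raises(ValueError, match="outside"):
            geo.rasterline_cells((0.5, 0.5), (99.0, 0.5), plain_grid)


def _pairs(*coords):
    return pd.DataFrame(
        [
            {"x_a": xa, "y_a": ya, "x_b": xb, "y_b": yb}
            for (xa, ya), (xb, yb) in coords
        ]
    )


class TestPathSummaries:
    def test_constant_layer_and_ones_distance(self, plain_grid):
        stack = RasterStack(grid=plain_grid)
        stack.add_layer("const", np.full(plain_grid.shape, 7.0))
        pairs = _pairs(((0.5, 10.5), (9.5, 10.5)))
        out = geo.path_summaries(stack, pairs)
        assert out.loc[0, "const"] == 7.0
        # geographic distance is exactly the path cell count (10 cells)
        assert out.loc[0, "geographic_distance"] == 10

    def test_median_skips_nodata(self, plain_grid):
        vals = np.zeros(plain_grid.shape)
        vals[9, 0:9] = np.arange(1, 10)
        stack = RasterStack(grid=plain_grid)
        stack.add_layer("v", vals)
        pairs = _pairs(((0.5, 10.5), (8.5, 10.5)))
        assert geo.path_summaries(stack, pairs).loc[0, "v"] == 5.0
        # knock out the middle cell: median of the remaining 8 values
        stack.mask[9, 4] = False
        expected = np.median([1, 2, 3, 4, 6, 7, 8, 9])
        assert geo.path_summaries(stack, pairs).loc[0, "v"] == expected

    def test_direction_invariance(self, small_stack):
        f = _pairs(((3.3, 12.1), (40.2, 30.7)))
        r = _pairs(((40.2, 30.7), (3.3, 12.1)))
        out_f = geo.path_summaries(small_stack, f)
        out_r = geo.path_summaries(small_stack, r)
        for name in small_stack.layer_names + ["geographic_distance"]:
            assert out_f.loc[0, name] == out_r.loc[0, name]

    def test_mostly_nodata_path_flagged(self, plain_grid):
        stack = RasterStack(grid=plain_grid)
        stack.add_layer("v", np.ones(plain_grid.shape))
        stack.mask[9, 0:8] = False  # 8 of 10 path cells invalid
        pairs = _pairs(((0.5, 10.5), (9.5, 10.5)))
        assert np.isnan(geo.path_summaries(stack, pairs).loc[0, "v"])


class TestKernelDensity:
    def test_single_point_peaks_in_containing_cell(self, plain_grid):
        dens = geo.kernel_density_raster([(10.2, 10.7)], bandwidth=2.0, grid=plain_grid)
        assert np.unravel_index(dens.argmax(), dens.shape) == plain_grid.cell_of(10.2, 10.7)
        assert (dens >= 0).all()

    def test_two_far_points_equal_maxima(self):
        grid = GridSpec(n_rows=40, n_cols=80, y_origin=40.0)
        dens = geo.kernel_density_raster(
            [(15.5, 20.5), (65.5, 20.5)], bandwidth=2.0, grid=grid
        )
        v1 = dens[grid.cell_of(15.5, 20.5)]
        v2 = dens[grid.cell_of(65.5, 20.5)]
        assert abs(v1 - v2) < 1e-6

    def test_integrates_to_one_away_from_edges(self):
        grid = GridSpec(n_rows=60, n_cols=60, y_origin=60.0)
        dens = geo.kernel_density_raster([(30.0, 30.0)], bandwidth=3.0, grid=grid)
        total = dens.sum() * grid.cell_size**2
        assert 0.9 <= total <= 1.0

    def test_empty_geometry_rejected(self, plain_grid):
        with pytest.raises(ValueError, match="empty"):
            geo.kernel_density_raster([], bandwidth=1.0, grid=plain_grid)

    def test_line_discretized(self, plain_grid):
        dens = geo.kernel_density_raster(
            [LineString([(2, 10), (25, 10)])], bandwidth=2.0, grid=plain_grid
        )
        # mass spread along the line: peak cells lie on the line's row
        assert np.unravel_index(dens.argmax(), dens.shape)[0] in (9, 10)


def naive_bioclim_cell(tmin, tmax, prec, seasons):
    """Scalar per-cell oracle with explicit loops (independent of the
    vectorized implementation)."""
    import statistics

    tavg = [(lo + hi) / 2 for lo, hi in zip(tmin, tmax)]
    out = {}
    out["bio01"] = sum(tavg) / 12
    out["bio02"] = sum(hi - lo for lo, hi in zip(tmin, tmax)) / 12
    out["bio04"] = 100 * statistics.stdev(tavg)
    out["bio05"] = max(tmax)
    out["bio06"] = min(tmin)
    out["bio07"] = out["bio05"] - out["bio06"]
    out["bio03"] = (
        100 * out["bio02"] / out["bio07"] if out["bio07"] != 0 else float("nan")
    )
    out["bio12"] = sum(prec)
    out["bio13"] = max(prec)
    out["bio14"] = min(prec)
    p1 = [p + 1 for p in prec]
    out["bio15"] = 100 * statistics.stdev(p1) / statistics.mean(p1)
    t_seas, p_seas = [], []
    for months in seasons.values():
        t_seas.append(statistics.mean(tavg[m - 1] for m in months))
        p_seas.append(sum(prec[m - 1] for m in months))
    wet = p_seas.index(max(p_seas))
    dry = p_seas.index(min(p_seas))
    warm = t_seas.index(max(t_seas))
    cold = t_seas.index(min(t_seas))
    out["bio08"], out["bio09"] = t_seas[wet], t_seas[dry]
    out["bio10"], out["bio11"] = t_seas[warm], t_seas[cold]
    out["bio16"], out["bio17"] = p_seas[wet], p_seas[dry]
    out["bio18"], out["bio19"] = p_seas[warm], p_seas[cold]
    return out


class TestBioclim:
    def test_constant_climate(self):
        shape = (3, 3)
        tmin = [np.full(shape, 18.0)] * 12
        tmax = [np.full(shape, 22.0)] * 12
        prec = [np.full(shape, 10.0)] * 12
        bio = geo.compute_bioclim(tmin, tmax, prec)
        assert np.allclose(bio["bio01"], 20.0)
        assert np.allclose(bio["bio04"], 0.0)
        assert np.allclose(bio["bio12"], 120.0)
        assert np.allclose(bio["bio15"], 0.0)

    def test_single_wet_month_with_disjoint_blocks(self):
        shape = (2, 2)
        tmin = [np.full(shape, 15.0)] * 12
        tmax = [np.full(shape, 25.0)] * 12
        prec = [np.zeros(shape) for _ in range(12)]
        prec[3] = np.full(shape, 120.0)  # April
        seasons = {
            "s1": [1, 2, 3], "s2": [4, 5, 6], "s3": [7, 8, 9], "s4": [10, 11, 12]
        }
        bio = geo.compute_bioclim(tmin, tmax, prec, seasons)
        assert np.allclose(bio["bio16"], 120.0)
        assert np.allclose(bio["bio17"], 0.0)

    @pytest.mark.parametrize("use_custom_seasons", [False, True])
    def test_matches_naive_scalar_oracle(self, use_custom_seasons):
        rng = np.random.default_rng(5)
        shape = (5, 5)
        tmin = [rng.uniform(5, 15, shape) for _ in range(12)]
        tmax = [t + rng.uniform(5, 15, shape) for t in tmin]
        prec = [rng.uniform(0, 200, shape) for _ in range(12)]
        if use_custom_seasons:
            seasons = {"a": [11, 12, 1, 2], "b": [3, 4, 5], "c": [6, 7, 8, 9, 10]}
        else:
            seasons = geo.default_seasons()
        bio = geo.compute_bioclim(tmin, tmax, prec, seasons)
        for r in range(shape[0]):
            for c in range(shape[1]):
                expected = naive_bioclim_cell(
                    [t[r, c] for t in tmin],
                    [t[r, c] for t in tmax],
                    [p[r, c] for p in prec],
                    seasons,
                )
                for name, val in expected.items():
                    assert bio[name][r, c] == pytest.approx(val, abs=1e-6), name

    def test_wrong_month_count_rejected(self):
        layers = [np.zeros((2, 2))] * 11
        with pytest.raises(ValueError, match="12 monthly"):
            geo.compute_bioclim(layers, layers, layers)

    def test_invalid_season_month_rejected(self):
        layers = [np.zeros((2, 2))] * 12
        with pytest.raises(ValueError, match="months"):
            geo.compute_bioclim(layers, layers, layers, {"bad": [0, 1]})


class TestMapAlgebra:
    def test_combine_max_idempotent_and_commutative(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 6))
        b = rng.normal(size=(6, 6))
        np.testing.assert_array_equal(geo.combine_max(a, a), a)
        np.testing.assert_array_equal(geo.combine_max(a, b), geo.combine_max(b, a))

    def test_combine_max_zero_floor(self):
        rng = np.random.default_rng(2)
        b = rng.normal(size=(4, 4))
        out = geo.combine_max(np.zeros((4, 4)), b)
        np.testing.assert_array_equal(out, np.clip(b, 0, None))

    def test_combine_max_nodata_policy(self):
        a = np.array([[1.0, np.nan], [np.nan, np.nan]])
        b = np.array([[0.5, 2.0], [np.nan, 3.0]])
        out = geo.combine_max(a, b)
        assert out[0, 0] == 1.0
        assert out[0, 1] == 2.0 and out[1, 1] == 3.0
        assert np.isnan(out[1, 0])

    def test_change_map(self):
        rng = np.random.default_rng(3)
        p = rng.normal(size=(5, 5))
        np.testing.assert_array_equal(geo.change_map(p, p), np.zeros((5, 5)))
        np.testing.assert_allclose(geo.change_map(p + 2, p), 2.0)
        np.testing.assert_array_equal(
            geo.change_map(p + 1, p), -geo.change_map(p, p + 1)
        )

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            geo.change_map(np.zeros((3, 3)), np.zeros((4, 4)))
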