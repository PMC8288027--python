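import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vectorscape import connectivity, geo, popgen, synthetic_data
from vectorscape.connectivity import DENSITY_FEATURE, DISTANCE_FEATURE, RESPONSE
from vectorscape.raster import RasterStack
from vectorscape.synthetic_data import SyntheticTruth


@pytest.fixture(scope="module")
def small_design():
    """A compact two-cluster design with a real resistance signal."""
    stack = synthetic_data.gen_landscape(4, 60, 80, corr_length=5, seed=31)
    truth = SyntheticTruth(divergence_rate=0.004, seed=31)
    sites, genotypes = synthetic_data.gen_sites_and_genotypes(
        stack, truth, n_sites_per_cluster=(7, 6), n_ind_per_site=25
    )
    dists = popgen.pairwise_cse(genotypes)
    density = geo.kernel_density_raster(
        list(zip(sites["x"], sites["y"])), bandwidth=10.0, grid=stack.grid
    )
    table = connectivity.assemble_path_features(sites, dists, stack, density)
    return stack, truth, sites, dists, density, table


class TestAssemblePathFeatures:
    def test_row_count_and_columns(self, small_design):
        stack, _, _, dists, _, table = small_design
        assert len(table) == len(dists) == 7 * 6 // 2 + 6 * 5 // 2
        for name in stack.layer_names + [DENSITY_FEATURE, DISTANCE_FEATURE, RESPONSE]:
            assert name in table.columns
        assert (table[DISTANCE_FEATURE] >= 1).all()

    def test_endpoint_order_irrelevant(self, small_design):
        stack, _, sites, dists, density, table = small_design
        swapped = dists.rename(columns={"site_a": "site_b", "site_b": "site_a"})
        table2 = connectivity.assemble_path_features(sites, swapped, stack, density)
        feats = connectivity.feature_columns(table)
        np.testing.assert_allclose(table[feats], table2[feats])

    def test_constant_layers_give_constant_features(self, small_design):
        _, _, sites, dists, density, _ = small_design
        grid = synthetic_data.gen_landscape(2, 60, 80, corr_length=5, seed=1).grid
        flat = RasterStack(grid=grid)
        flat.add_layer("flat1", np.full(grid.shape, 2.0))
        flat.add_layer("flat2", np.full(grid.shape, -1.0))
        table = connectivity.assemble_path_features(sites, dists, flat, density)
        assert table["flat1"].nunique() == 1
        assert table["flat2"].nunique() == 1
        # signal can then only come from distance/density
        assert table[DISTANCE_FEATURE].nunique() > 1

    def test_unknown_site_rejected(self, small_design):
        stack, _, sites, dists, density, _ = small_design
        bad = dists.copy()
        bad.loc[0, "site_a"] = "nowhere"
        with pytest.raises(ValueError, match="nowhere"):
            connectivity.assemble_path_features(sites, bad, stack, density)


class TestLooSiteCV:
    def test_one_run_per_site(self, small_design):
        *_, table = small_design
        runs = connectivity.loo_site_cv(table, n_trees=25, seed=0)
        assert set(runs["site"]) == set(table["site_a"]) | set(table["site_b"])
        assert (runs["rmse"] >= 0).all()

    def test_constant_response_gives_zero_rmse(self, small_design):
        *_, table = small_design
        flat = table.copy()
        flat[RESPONSE] = 0.25
        runs = connectivity.loo_site_cv(flat, n_trees=25, seed=0)
        np.testing.assert_allclose(runs["rmse"], 0.0, atol=1e-12)

    def test_deterministic_under_seed(self, small_design):
        *_, table = small_design
        r1 = connectivity.loo_site_cv(table, n_trees=25, seed=5)
        r2 = connectivity.loo_site_cv(table, n_trees=25, seed=5)
        pd.testing.assert_frame_equal(r1, r2)


class TestNullRmse:
    def test_null_count_and_determinism(self, small_design):
        *_, table = small_design
        n1 = connectivity.null_rmse(table, n_null=5, n_trees=25, seed=2)
        n2 = connectivity.null_rmse(table, n_null=5, n_trees=25, seed=2)
        assert len(n1.null_rmse) == 5
        np.testing.assert_array_equal(n1.null_rmse, n2.null_rmse)
        assert n1.p_value == n2.p_value

    def test_welch_separated_samples(self):
        rng = np.random.default_rng(0)
        obs = 0.06 + rng.normal(0, 1e-6, 15)
        null = 0.11 + rng.normal(0, 1e-6, 100)
        res = stats.ttest_ind(obs, null, equal_var=False, alternative="less")
        assert res.statistic < 0
        assert res.pvalue < 1e-6

    def test_too_few_replicates_rejected(self, small_design):
        *_, table = small_design
        with pytest.raises(ValueError, match="at least 2"):
            connectivity.null_rmse(table, n_null=1, n_trees=10)

    def test_signal_beats_null(self, small_design):
        """With real isolation-by-resistance structure the observed LOO
        error should undercut the shuffled-response null."""
        *_, table = small_design
        null = connectivity.null_rmse(table, n_null=10, n_trees=50, seed=3)
        assert null.observed["rmse"].mean() < null.null_rmse.mean()
        assert null.p_value < 0.05


class TestProjection:
    def test_constant_layers_give_constant_surface(self, small_design):
        _, _, sites, dists, density, table = small_design
        grid = synthetic_data.gen_landscape(2, 60, 80, corr_length=5, seed=1).grid
        flat = RasterStack(grid=grid)
        flat.add_layer("flat1", np.full(grid.shape, 2.0))
        flat.add_layer("flat2", np.full(grid.shape, -1.0))
        ftable = connectivity.assemble_path_features(sites, dists, flat, density)
        model = connectivity.fit_connectivity(ftable, n_trees=25, seed=0)
        flat_density = np.full(grid.shape, 0.5)
        surface = connectivity.project_connectivity(model, flat, flat_density)
        vals = surface[np.isfinite(surface)]
        assert np.ptp(vals) < 1e-12

    def test_output_within_training_range(self, small_design):
        stack, _, _, _, density, table = small_design
        model = connectivity.fit_connectivity(table, n_trees=50, seed=0)
        surface = connectivity.project_connectivity(model, stack, density)
        vals = surface[np.isfinite(surface)]
        assert vals.min() >= table[RESPONSE].min() - 1e-12
        assert vals.max() <= table[RESPONSE].max() + 1e-12

    def test_surface_tracks_true_resistance_driver(self, small_design):
        stack, truth, _, _, density, table = small_design
        model = connectivity.fit_connectivity(table, n_trees=100, seed=1)
        surface = connectivity.project_connectivity(model, stack, density)
        driver = next(iter(truth.resistance_coefficients))
        ok = np.isfinite(surface)
        r, p = stats.pearsonr(surface[ok], stack[driver][ok])
        assert r > 0 and p < 0.01

    def test_missing_layer_rejected(self, small_design):
        stack, _, _, _, density, table = small_design
        model = connectivity.fit_connectivity(table, n_trees=10, seed=0)
        partial = RasterStack(grid=stack.grid, mask=stack.mask.copy())
        partial.add_layer("env01", stack["env01"])
        with pytest.raises(ValueError, match="env02"):
            connectivity.project_connectivity(model, partial, density)


class TestSpatialEvaluate:
    def test_constant_surface_closed_form(self, small_design):
        stack, _, sites, dists, _, _ = small_design
        c = 0.2
        surface = np.full(stack.grid.shape, c)
        site = dists["site_a"].iloc[0]
        rmse = connectivity.spatial_evaluate(surface, sites, dists, site, stack=stack)
        test = dists[(dists["site_a"] == site) | (dists["site_b"] == site)]
        expected = np.sqrt(np.mean((test["cse"] - c) ** 2))
        assert rmse == pytest.approx(expected, abs=1e-12)
        # all observed equal to the constant -> RMSE exactly zero
        flat = dists.copy()
        flat["cse"] = c
        assert connectivity.spatial_evaluate(
            surface, sites, flat, site, stack=stack
        ) == pytest.approx(0.0, abs=1e-15)

    def test_direction_invariance(self, small_design):
        stack, _, sites, dists, density, table = small_design
        model = connectivity.fit_connectivity(table, n_trees=25, seed=0)
        surface = connectivity.project_connectivity(model, stack, density)
        site = dists["site_a"].iloc[0]
        swapped = dists.rename(columns={"site_a": "site_b", "site_b": "site_a"})
        r1 = connectivity.spatial_evaluate(surface, sites, dists, site, stack=stack)
        r2 = connectivity.spatial_evaluate(surface, sites, swapped, site, stack=stack)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_unknown_site_rejected(self, small_design):
        stack, _, sites, dists, _, _ = small_design
        surface = np.zeros(stack.grid.shape)
        with pytest.raises(ValueError, match="nowhere"):
            connectivity.spatial_evaluate(surface, sites, dists, "nowhere", stack=stack)


def test_spatial_and_model_predictions_agree_in_degenerate_case(small_design):
    """With constant environment and density, the projected surface is the
    model's single prediction everywhere, so path-median spatial predictions
    coincide with direct model predictions at geographic distance 1."""
    _, _, sites, dists, _, _ = small_design
    grid = synthetic_data.gen_landscape(2, 60, 80, corr_length=5, seed=1).grid
    flat = RasterStack(grid=grid)
    flat.add_layer("flat1", np.full(grid.shape, 2.0))
    flat.add_layer("flat2", np.full(grid.shape, -1.0))
    flat_density = np.full(grid.shape, 0.5)
    table = connectivity.assemble_path_features(sites, dists, flat, flat_density)
    table[DISTANCE_FEATURE] = 1  # train at the projection's distance convention
    model = connectivity.fit_connectivity(table, n_trees=25, seed=0)
    surface = connectivity.project_connectivity(model, flat, flat_density)
    site = dists["site_a"].iloc[0]
    rmse_map = connectivity.spatial_evaluate(surface, sites, dists, site, stack=flat)
    test = (table["site_a"] == site) | (table["site_b"] == site)
    pred = model.predict(table[test])
    rmse_direct = np.sqrt(np.mean((pred - table.loc[test, RESPONSE]) ** 2))
    assert rmse_map == pytest.approx(rmse_direct, abs=1e-12)
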