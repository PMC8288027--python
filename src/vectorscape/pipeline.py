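"""End-to-end orchestration of the synthetic study.

``run_full`` generates a truth-known landscape, runs both model branches
(suitability from presence/background points; connectivity from pairwise
chord distances and path features), integrates them into the bivariate
map, runs the post hoc local-correlation and environmental-change
analyses, and writes every table as CSV and every surface as an ASCII
grid.  The same entry point backs the command-line interface, the
acceptance script, and the end-to-end determinism test.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import connectivity as conn_mod
from . import geo, integrate, popgen, suitability, synthetic_data
from .config import PipelineConfig
from .raster import RasterStack, write_ascii_grid

logger = logging.getLogger(__name__)


def make_truth(config: PipelineConfig, seed: int) -> synthetic_data.SyntheticTruth:
    return synthetic_data.SyntheticTruth(
        driver_layer_names=[config.suitability_driver, config.resistance_driver],
        suitability_coefficients={config.suitability_driver: config.suitability_weight},
        resistance_coefficients={config.resistance_driver: config.resistance_weight},
        divergence_rate=config.divergence_rate,
        seed=seed,
        suitability_intercept=config.suitability_intercept,
    )


def simulate(config: PipelineConfig, seed: int):
    """Landscape, truth, sites, genotypes and presence points."""
    stack = synthetic_data.gen_landscape(
        n_layers=config.n_layers,
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        corr_length=config.corr_length,
        seed=seed,
        nodata_fraction=config.nodata_fraction,
        cell_size=config.cell_size,
    )
    truth = make_truth(config, seed)
    sites, genotypes = synthetic_data.gen_sites_and_genotypes(
        stack,
        truth,
        n_sites_per_cluster=config.n_sites_per_cluster,
        n_ind_per_site=config.n_ind_per_site,
        n_loci=config.n_loci,
        n_alleles=config.n_alleles,
    )
    presences = synthetic_data.gen_presence(
        stack, truth, n_points=config.n_presence, seed=seed + 1
    )
    return stack, truth, sites, genotypes, presences


def run_full(
    config: PipelineConfig, seed: int, outdir: str | Path | None = None
) -> dict:
    """Run the whole pipeline; returns a results dictionary and optionally
    writes all tables/surfaces under ``outdir``."""
    stack, truth, sites, genotypes, presences = simulate(config, seed)

    # ---- connectivity branch
    dists = popgen.pairwise_cse(genotypes, variant=config.cse_variant)
    density = geo.kernel_density_raster(
        list(zip(sites["x"], sites["y"])),
        bandwidth=config.kde_bandwidth_cells * config.cell_size,
        grid=stack.grid,
    )
    paths = conn_mod.assemble_path_features(sites, dists, stack, density)
    cparams = config.connectivity_forest.kwargs()
    nparams = config.cv_forest.kwargs()
    conn_model = conn_mod.fit_connectivity(paths, seed=seed, **cparams)
    observed = conn_mod.loo_site_cv(paths, seed=seed, **nparams)
    null = conn_mod.null_rmse(
        paths, n_null=config.n_null, seed=seed, observed=observed, **nparams
    )
    conn_surface = conn_mod.project_connectivity(conn_model, stack, density)
    spatial = pd.DataFrame(
        {
            "site": observed["site"],
            "rmse": [
                conn_mod.spatial_evaluate(conn_surface, sites, dists, s, stack=stack)
                for s in observed["site"]
            ],
        }
    )

    # ---- suitability branch
    background = suitability.sample_background_replicates(
        config.n_background,
        stack,
        n_replicates=config.n_background_replicates,
        seed=seed + 2,
    )
    sparams = config.suitability_forest.kwargs()
    suit_models, suit_metrics, suit_surface = suitability.fit_suitability_replicates(
        presences, background, stack, k=config.k_folds, seed=seed, **sparams
    )

    # ---- integration
    suit_scaled = integrate.scale01(suit_surface)
    conn_scaled = 1.0 - integrate.scale01(conn_surface)
    low = integrate.mask_low_suitability(suit_surface, config.mask_threshold)
    bimap = integrate.bivariate_classify(
        suit_scaled, conn_scaled, n_classes=config.n_bivariate_classes, masked=low
    )

    # ---- post hoc: local correlations with each model's top predictor and
    # synthetic future-change maps for those predictors
    suit_importance = (
        pd.concat([m.importance for m in suit_models], axis=1).mean(axis=1)
    )
    top_suit = suit_importance.idxmax()
    top_conn = conn_model.importance.drop(
        index=[conn_mod.DISTANCE_FEATURE, conn_mod.DENSITY_FEATURE],
        errors="ignore",
    ).idxmax()
    local_r = {
        ("suitability", top_suit): integrate.local_correlation(
            suit_surface, stack[top_suit], window=config.correlation_window, masked=low
        ),
        ("connectivity", top_conn): integrate.local_correlation(
            conn_surface, stack[top_conn], window=config.correlation_window, masked=low
        ),
    }
    rng = np.random.default_rng(seed + 3)
    change = {}
    for name in {top_suit, top_conn}:
        delta = ndimage.gaussian_filter(
            rng.standard_normal(stack.grid.shape), sigma=config.corr_length
        )
        delta = 0.5 * delta / max(delta.std(), 1e-12)
        future = stack[name] + delta
        cmap = geo.change_map(future, stack[name])
        cmap[low] = np.nan
        change[name] = cmap

    results = {
        "config": config,
        "truth": truth,
        "stack": stack,
        "sites": sites,
        "genotypes": genotypes,
        "presences": presences,
        "distances": dists,
        "path_features": paths,
        "connectivity_model": conn_model,
        "loo_rmse": observed,
        "null_eval": null,
        "spatial_rmse": spatial,
        "connectivity_surface": conn_surface,
        "suitability_models": suit_models,
        "suitability_metrics": suit_metrics,
        "suitability_surface": suit_surface,
        "suitability_importance": suit_importance,
        "bivariate": bimap,
        "local_correlation": local_r,
        "change_maps": change,
        "summary": {
            "n_paths": int(len(paths)),
            "suitability_mean_oob_r2": float(
                np.mean([m.oob_r2 for m in suit_models])
            ),
            "suitability_mean_auc": float(suit_metrics["auc"].mean()),
            "suitability_mean_tss": float(suit_metrics["tss"].mean()),
            "suitability_top_variable": str(top_suit),
            "connectivity_oob_r2": float(conn_model.oob_r2),
            "connectivity_top_variable": str(top_conn),
            "loo_mean_rmse": float(observed["rmse"].mean()),
            "loo_sd_rmse": float(observed["rmse"].std(ddof=1)),
            "null_mean_rmse": float(null.null_rmse.mean()),
            "null_sd_rmse": float(null.null_rmse.std(ddof=1)),
            "welch_t": null.t_stat,
            "welch_df": null.df,
            "welch_p": null.p_value,
            "spatial_mean_rmse": float(spatial["rmse"].mean()),
        },
    }
    if outdir is not None:
        write_outputs(results, Path(outdir))
    return results


def write_outputs(results: dict, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack: RasterStack = results["stack"]
    grid = stack.grid
    stack.write_dir(outdir / "landscape")
    results["truth"].to_yaml(outdir / "truth.yml")
    results["sites"].to_csv(outdir / "sites.csv", index=False)
    popgen.write_genotypes_csv(results["genotypes"], outdir / "genotypes.csv")
    popgen.write_genepop(results["genotypes"], outdir / "genotypes.gen")
    results["presences"].to_csv(outdir / "presences.csv", index=False)
    results["distances"].to_csv(outdir / "cse_distances.csv", index=False)
    popgen.distance_matrix(results["distances"]).to_csv(outdir / "cse_matrix.csv")
    results["path_features"].to_csv(outdir / "path_features.csv", index=False)
    results["loo_rmse"].to_csv(outdir / "loo_rmse.csv", index=False)
    pd.DataFrame({"null_rmse": results["null_eval"].null_rmse}).to_csv(
        outdir / "null_rmse.csv", index=False
    )
    results["spatial_rmse"].to_csv(outdir / "spatial_rmse.csv", index=False)
    results["suitability_metrics"].to_csv(
        outdir / "suitability_metrics.csv", index=False
    )
    results["suitability_importance"].rename("importance").to_csv(
        outdir / "suitability_importance.csv"
    )
    results["connectivity_model"].importance.rename("importance").to_csv(
        outdir / "connectivity_importance.csv"
    )
    write_ascii_grid(
        outdir / "suitability.asc", results["suitability_surface"], grid
    )
    write_ascii_grid(
        outdir / "connectivity_distance.asc", results["connectivity_surface"], grid
    )
    bimap = results["bivariate"]
    write_ascii_grid(outdir / "bivariate_classes.asc", bimap.classes.astype(float), grid)
    bimap.legend.to_csv(outdir / "bivariate_legend.csv", index=False)
    for (branch, layer), arr in results["local_correlation"].items():
        write_ascii_grid(outdir / f"local_r_{branch}_{layer}.asc", arr, grid)
    for layer, arr in results["change_maps"].items():
        write_ascii_grid(outdir / f"change_{layer}.asc", arr, grid)
    with open(outdir / "summary.yml", "w") as fh:
        yaml.safe_dump(results["summary"], fh, sort_keys=False)
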