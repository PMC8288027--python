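"""Genetic-connectivity modeling from path features.

Pairwise chord distance between sampling sites (within genetic clusters)
is regressed on the median environmental values along the straight path
between each pair, the median sampling-effort kernel density along the
path, and the geographic distance (path cell count on a 1-km grid).  The
fitted forest is projected per pixel with geographic distance fixed at 1,
which reads as "the predicted genetic distance across a single kilometre
of this environment" — low values mean high connectivity.

Evaluation is leave-one-site-out: all pairs touching the held-out site
form the test set, giving one RMSE per site.  The observed RMSE
distribution is compared against RMSEs from forests trained on randomly
shuffled responses (the null: no environmental signal) with a one-sided
Welch t test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import geo
from .forest import ModelResult, fit_rf_regression, make_forest
from .raster import RasterStack

logger = logging.getLogger(__name__)

DENSITY_FEATURE = "sampling_density"
DISTANCE_FEATURE = "geographic_distance"
RESPONSE = "cse"
_META_COLUMNS = ("site_a", "site_b", "cluster", RESPONSE)


@dataclass
class NullEval:
    """Observed vs shuffled-response RMSE distributions."""

    observed: pd.DataFrame  # per-site RMSE (columns: site, n_test, rmse)
    null_rmse: np.ndarray  # one mean RMSE per shuffled replicate
    t_stat: float
    df: float
    p_value: float  # one-sided, observed < null


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLUMNS]


def assemble_path_features(
    sites: pd.DataFrame,
    dists: pd.DataFrame,
    stack: RasterStack,
    density: np.ndarray,
) -> pd.DataFrame:
    """One row per within-cluster site pair: path medians of every
    environmental layer and of the sampling-density layer, geographic
    distance, and the observed chord distance as response.

    Pairs whose path is mostly nodata for any layer are dropped (logged).
    """
    coords = sites.set_index("site_id")[["x", "y"]]
    missing_sites = (set(dists["site_a"]) | set(dists["site_b"])) - set(coords.index)
    if missing_sites:
        raise ValueError(f"distance table references unknown sites: {sorted(missing_sites)}")

    work = stack.copy()
    work.add_layer(DENSITY_FEATURE, density)
    pairs = dists.copy()
    pairs["x_a"] = coords.loc[pairs["site_a"], "x"].to_numpy()
    pairs["y_a"] = coords.loc[pairs["site_a"], "y"].to_numpy()
    pairs["x_b"] = coords.loc[pairs["site_b"], "x"].to_numpy()
    pairs["y_b"] = coords.loc[pairs["site_b"], "y"].to_numpy()
    table = geo.path_summaries(work, pairs)
    table = table.drop(columns=["x_a", "y_a", "x_b", "y_b"])
    feats = [c for c in table.columns if c not in _META_COLUMNS]
    ok = table[feats].notna().all(axis=1)
    if (~ok).any():
        logger.warning(
            "assemble_path_features: dropped %d pair(s) with nodata-dominated paths",
            int((~ok).sum()),
        )
    table = table[ok].reset_index(drop=True)
    # response last for readability
    return table[
        ["site_a", "site_b", "cluster"]
        + [c for c in feats]
        + [RESPONSE]
    ]


def fit_connectivity(
    table: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    max_features: float = 1.0 / 3.0,
    min_samples_leaf: int = 5,
) -> ModelResult:
    return fit_rf_regression(
        table,
        response=RESPONSE,
        features=feature_columns(table),
        n_trees=n_trees,
        seed=seed,
        max_features=max_features,
        min_samples_leaf=min_samples_leaf,
    )


# ---------------------------------------------------------------- LOO CV


def loo_site_cv(
    table: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    max_features: float = 1.0 / 3.0,
    min_samples_leaf: int = 5,
) -> pd.DataFrame:
    """Leave-one-site-out cross-validation: one run (and one RMSE) per
    site, with every pair touching the held-out site as the test set."""
    feats = feature_columns(table)
    y = table[RESPONSE].to_numpy(dtype=float)
    X = table[feats].to_numpy(dtype=float)
    sites = sorted(set(table["site_a"]) | set(table["site_b"]), key=str)
    records = []
    for i, site in enumerate(sites):
        test = ((table["site_a"] == site) | (table["site_b"] == site)).to_numpy()
        if not test.any():
            logger.warning("loo_site_cv: site %r has no pairs, skipped", site)
            continue
        model = make_forest(
            n_trees=n_trees,
            seed=seed + i,
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
        ).fit(X[~test], y[~test])
        pred = model.predict(X[test])
        rmse = float(np.sqrt(np.mean((pred - y[test]) ** 2)))
        records.append({"site": site, "n_test": int(test.sum()), "rmse": rmse})
    return pd.DataFrame.from_records(records)


def null_rmse(
    table: pd.DataFrame,
    n_null: int = 100,
    n_trees: int = 500,
    seed: int = 0,
    max_features: float = 1.0 / 3.0,
    min_samples_leaf: int = 5,
    observed: pd.DataFrame | None = None,
) -> NullEval:
    """Shuffled-response null distribution of LOO RMSEs plus Welch t test.

    Each null replicate permutes the response column jointly over all pairs,
    reruns the leave-one-site-out procedure, and is summarized as the mean
    of its per-site RMSEs, giving ``n_null`` null values.  Welch's
    two-sample t test (unequal variances) compares the observed per-site
    RMSEs against the null values, one-sided with alternative
    observed < null.
    """
    if n_null < 2:
        raise ValueError(f"need at least 2 null replicates, got {n_null}")
    if observed is None:
        observed = loo_site_cv(
            table,
            n_trees=n_trees,
            seed=seed,
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
        )
    rng = np.random.default_rng(seed)
    nulls = []
    shuffled = table.copy()
    for rep in range(n_null):
        shuffled[RESPONSE] = rng.permutation(table[RESPONSE].to_numpy())
        run = loo_site_cv(
            shuffled,
            n_trees=n_trees,
            seed=seed + 1000 + rep,
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
        )
        nulls.append(float(run["rmse"].mean()))
    nulls = np.array(nulls)
    res = stats.ttest_ind(
        observed["rmse"].to_numpy(), nulls, equal_var=False, alternative="less"
    )
    return NullEval(
        observed=observed,
        null_rmse=nulls,
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


# ------------------------------------------------------------- projection


def project_connectivity(
    m: ModelResult, stack: RasterStack, density: np.ndarray
) -> np.ndarray:
    """Per-pixel predicted chord distance with geographic distance = 1.

    Each pixel supplies its own layer values and density value; the
    output inherits the forest-mean bound (within the training response
    range).  NaN on masked cells.
    """
    rows, cols = np.nonzero(stack.mask)
    columns = {}
    for name in m.features:
        if name == DISTANCE_FEATURE:
            columns[name] = np.ones(len(rows))
        elif name == DENSITY_FEATURE:
            columns[name] = np.asarray(density, dtype=float)[rows, cols]
        elif name in stack.layers:
            columns[name] = stack[name][rows, cols]
        else:
            raise ValueError(f"stack is missing model feature layer {name!r}")
    X = np.column_stack([columns[name] for name in m.features])
    out = np.full(stack.grid.shape, np.nan)
    out[rows, cols] = m.model.predict(X)
    return out


def spatial_evaluate(
    surface: np.ndarray,
    sites: pd.DataFrame,
    dists: pd.DataFrame,
    left_out,
    grid=None,
    stack: RasterStack | None = None,
) -> float:
    """RMSE of path-median surface predictions for the pairs touching the
    held-out site (the map-level analogue of the LOO model evaluation)."""
    if stack is None:
        if grid is None:
            raise ValueError("provide either stack or grid")
        stack = RasterStack(grid=grid, mask=np.isfinite(np.asarray(surface, float)))
    work = RasterStack(grid=stack.grid, mask=stack.mask.copy())
    work.add_layer("surface", surface)
    test = dists[(dists["site_a"] == left_out) | (dists["site_b"] == left_out)]
    if test.empty:
        raise ValueError(f"no pairs involve site {left_out!r}")
    coords = sites.set_index("site_id")[["x", "y"]]
    pairs = test.copy()
    pairs["x_a"] = coords.loc[pairs["site_a"], "x"].to_numpy()
    pairs["y_a"] = coords.loc[pairs["site_a"], "y"].to_numpy()
    pairs["x_b"] = coords.loc[pairs["site_b"], "x"].to_numpy()
    pairs["y_b"] = coords.loc[pairs["site_b"], "y"].to_numpy()
    summ = geo.path_summaries(work, pairs, layers=["surface"])
    ok = summ["surface"].notna()
    if (~ok).any():
        logger.warning(
            "spatial_evaluate: dropped %d pair(s) with nodata-dominated paths",
            int((~ok).sum()),
        )
    summ = summ[ok]
    if summ.empty:
        raise ValueError(f"all paths for site {left_out!r} are nodata")
    return float(
        np.sqrt(np.mean((summ["surface"] - summ[RESPONSE]) ** 2))
    )
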