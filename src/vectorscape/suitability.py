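"""Habitat-suitability modeling from presence/background points.

Presence cells (trap locations that caught flies) are scored 1 and random
background cells 0; a regression forest on the environmental layer values
at those cells then yields a continuous suitability score in [0, 1].  The
standard design is 10 replicates of 100 background points, giving 10
replicate models whose per-pixel mean is the reported suitability surface;
each replicate is evaluated by stratified 10-fold cross-validation with
AUC and the true skill statistic (TSS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .forest import ModelResult, fit_rf_regression, make_forest
from .raster import RasterStack

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    """Per-fold discrimination metrics for one training table."""

    folds: pd.DataFrame  # columns: fold, auc, tss, threshold

    @property
    def mean_auc(self) -> float:
        return float(self.folds["auc"].mean())

    @property
    def mean_tss(self) -> float:
        return float(self.folds["tss"].mean())


# ---------------------------------------------------------- point sampling


def sample_background(
    n: int,
    stack: RasterStack,
    seed: int,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """``n`` background cells uniform over eligible cells, without
    replacement at cell granularity; returns cell-center coordinates."""
    eligible = stack.mask if mask is None else (stack.mask & np.asarray(mask, bool))
    rows, cols = np.nonzero(eligible)
    if len(rows) == 0:
        raise ValueError("background mask excludes every cell")
    if n > len(rows):
        raise ValueError(f"{n} background points requested, {len(rows)} cells eligible")
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(len(rows), size=n, replace=False))
    xy = np.array(
        [stack.grid.cell_center(r, c) for r, c in zip(rows[pick], cols[pick])]
    )
    return pd.DataFrame(
        {"x": xy[:, 0], "y": xy[:, 1], "row": rows[pick], "col": cols[pick]}
    )


def sample_background_replicates(
    n: int,
    stack: RasterStack,
    n_replicates: int,
    seed: int,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Replicate background sets with seeds derived from one base seed."""
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    frames = []
    for rep, s in enumerate(seeds):
        df = sample_background(n, stack, seed=int(s % (2**31)), mask=mask)
        df.insert(0, "replicate", rep)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def assemble_presence_background(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    stack: RasterStack,
    layers: list[str] | None = None,
) -> pd.DataFrame:
    """Training table: response 1/0 plus per-layer values at cell centers.

    Presences are deduplicated to one per grid cell before feature
    extraction; rows landing on nodata for any layer are dropped (logged).
    """
    layers = list(layers) if layers is not None else stack.layer_names

    def cells_of(df: pd.DataFrame) -> pd.DataFrame:
        if {"row", "col"}.issubset(df.columns):
            return df[["row", "col"]].astype(int)
        rc = [stack.grid.cell_of(x, y) for x, y in zip(df["x"], df["y"])]
        return pd.DataFrame(rc, columns=["row", "col"], index=df.index)

    pres_cells = cells_of(presences).drop_duplicates()
    back_cells = cells_of(background)
    if pres_cells.empty:
        raise ValueError("no presence cells left after deduplication")

    parts = []
    for cells, label in ((pres_cells, 1.0), (back_cells, 0.0)):
        feat = {"response": np.full(len(cells), label)}
        for name in layers:
            feat[name] = stack.values_at(
                name, cells["row"].to_numpy(), cells["col"].to_numpy()
            )
        part = pd.DataFrame(feat, index=cells.index)
        part[["row", "col"]] = cells
        parts.append(part)
    table = pd.concat(parts, ignore_index=True)
    ok = table[layers].notna().all(axis=1)
    if (~ok).any():
        logger.warning(
            "assemble_presence_background: dropped %d point(s) on nodata cells",
            int((~ok).sum()),
        )
    table = table[ok].reset_index(drop=True)
    if (table["response"] == 1).sum() == 0:
        raise ValueError("no presence rows survive nodata filtering")
    return table


# ------------------------------------------------------------- evaluation


def tss_from_scores(
    y: np.ndarray, scores: np.ndarray
) -> tuple[float, float]:
    """Maximum true skill statistic (sensitivity + specificity - 1) over
    all score thresholds, and the threshold achieving it."""
    fpr, tpr, thresholds = roc_curve(y, scores)
    tss = tpr - fpr
    best = int(np.argmax(tss))
    return float(tss[best]), float(thresholds[best])


def evaluate_cv(
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    max_features: float = 1.0 / 3.0,
    min_samples_leaf: int = 5,
    features: list[str] | None = None,
) -> EvalResult:
    """Stratified k-fold cross-validation with AUC and TSS per fold.

    AUC is the rank-based probability that a presence outscores a
    background point (ties count one half).
    """
    if features is None:
        features = [
            c for c in table.columns if c not in ("response", "row", "col")
        ]
    y = table["response"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for cross-validation")
    X = table[features].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    records = []
    for fold, (train, test) in enumerate(skf.split(X, y)):
        model = make_forest(
            n_trees=n_trees,
            seed=seed + fold,
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
        ).fit(X[train], y[train])
        scores = model.predict(X[test])
        auc = float(roc_auc_score(y[test], scores))
        tss, threshold = tss_from_scores(y[test], scores)
        records.append(
            {"fold": fold, "auc": auc, "tss": tss, "threshold": threshold}
        )
    return EvalResult(folds=pd.DataFrame.from_records(records))


# ------------------------------------------------------------- projection


def project_suitability(m: ModelResult, stack: RasterStack) -> np.ndarray:
    """Per-pixel forest prediction over unmasked cells (NaN elsewhere).

    Predictions are means of 0/1 leaf values, hence bounded in [0, 1]."""
    missing = [f for f in m.features if f not in stack.layers]
    if missing:
        raise ValueError(f"stack is missing model feature layer(s): {missing}")
    rows, cols = np.nonzero(stack.mask)
    X = np.column_stack([stack[name][rows, cols] for name in m.features])
    out = np.full(stack.grid.shape, np.nan)
    out[rows, cols] = m.model.predict(X)
    return out


def fit_suitability_replicates(
    presences: pd.DataFrame,
    background_replicates: pd.DataFrame,
    stack: RasterStack,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    max_features: float = 1.0 / 3.0,
    min_samples_leaf: int = 5,
    layers: list[str] | None = None,
) -> tuple[list[ModelResult], pd.DataFrame, np.ndarray]:
    """One model per background replicate; reported surface is the
    per-pixel mean of the replicate projections.

    Returns (models, metrics table with replicate/fold rows, mean surface).
    """
    models: list[ModelResult] = []
    metric_frames = []
    surface = np.zeros(stack.grid.shape)
    replicates = sorted(background_replicates["replicate"].unique())
    for rep in replicates:
        back = background_replicates[background_replicates["replicate"] == rep]
        table = assemble_presence_background(presences, back, stack, layers=layers)
        result = fit_rf_regression(
            table.drop(columns=["row", "col"]),
            response="response",
            n_trees=n_trees,
            seed=seed + rep,
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
        )
        ev = evaluate_cv(
            table,
            k=k,
            seed=seed + rep,
            n_trees=n_trees,
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
        )
        fold_df = ev.folds.copy()
        fold_df.insert(0, "replicate", rep)
        fold_df["oob_r2"] = result.oob_r2
        metric_frames.append(fold_df)
        models.append(result)
        surface += project_suitability(result, stack)
    surface /= len(replicates)
    surface[~stack.mask] = np.nan
    return models, pd.concat(metric_frames, ignore_index=True), surface
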