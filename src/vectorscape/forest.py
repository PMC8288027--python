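"""Random-forest regression wrapper shared by the suitability and
connectivity models.

Both models follow the randomForest-regression conventions: ``mtry`` of
p/3 features per split, out-of-bag R², and variable importance measured as
increase in node purity — the total decrease in residual sum of squares
from splits on a variable, averaged over trees.  Node-purity importance is
preferred over permutation importance because it is not inflated by
correlation between predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

DEFAULT_FOREST_PARAMS = {
    "n_trees": 500,
    "max_features": 1.0 / 3.0,  # fraction of features per split (floor)
    "min_samples_leaf": 5,
}


@dataclass
class ModelResult:
    """Fitted forest plus its internal goodness-of-fit summaries."""

    model: RandomForestRegressor
    oob_r2: float
    importance: pd.Series  # variable -> impurity (RSS) decrease, tree-averaged
    params: dict = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.importance.index)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict(table[self.features].to_numpy())


def make_forest(
    n_trees: int = 500,
    seed: int = 0,
    max_features: float = 1.0 / 3.0,
    min_samples_leaf: int = 5,
    oob_score: bool = False,
) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features,
        min_samples_leaf=min_samples_leaf,
        oob_score=oob_score,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def impurity_importance(model: RandomForestRegressor, features: list[str]) -> pd.Series:
    """Unnormalized RSS-decrease importance averaged across trees.

    sklearn's ``feature_importances_`` rescales each tree to sum to one;
    here the raw per-tree impurity decreases are averaged instead, matching
    the increase-in-node-purity scores of classic regression forests up to
    a constant factor.
    """
    per_tree = np.array(
        [
            tree.tree_.compute_feature_importances(normalize=False)
            for tree in model.estimators_
        ]
    )
    return pd.Series(per_tree.mean(axis=0), index=features)


def fit_rf_regression(
    table: pd.DataFrame,
    response: str,
    features: list[str] | None = None,
    n_trees: int = 500,
    seed: int = 0,
    max_features: float = 1.0 / 3.0,
    min_samples_leaf: int = 5,
) -> ModelResult:
    """Fit a regression forest and report OOB R² and node-purity importance.

    OOB R² is 1 - MSE_oob / Var(response), the forest's internal
    bootstrap-based estimate of explained variance.
    """
    if features is None:
        features = [c for c in table.columns if c != response]
    if len(table) < 20:
        raise ValueError(f"need at least 20 rows to fit, got {len(table)}")
    if len(features) < 2:
        raise ValueError(f"need at least 2 features, got {len(features)}")
    y = table[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant; nothing to model")
    X = table[features].to_numpy(dtype=float)
    model = make_forest(
        n_trees=n_trees,
        seed=seed,
        max_features=max_features,
        min_samples_leaf=min_samples_leaf,
        oob_score=True,
    ).fit(X, y)
    return ModelResult(
        model=model,
        oob_r2=float(model.oob_score_),
        importance=impurity_importance(model, features),
        params={
            "n_trees": n_trees,
            "max_features": max_features,
            "min_samples_leaf": min_samples_leaf,
            "seed": seed,
            "response": response,
        },
    )
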