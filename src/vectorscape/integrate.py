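"""Bivariate suitability × connectivity mapping and post hoc analyses.

The two model surfaces are min-max scaled to [0, 1]; connectivity is
1 - scaled predicted genetic distance so that high values mean easy gene
flow.  Cells whose predicted probability of presence is below ten percent
are masked out of every downstream map (no point planning control where
the fly is absent).  The bivariate map cuts each surface into quantile
classes (3 per axis by default) and encodes the class pair per cell; the
corner classes carry the planning semantics (high/high: control works and
reinvasion risk is high; high suitability/low connectivity: local control
can last; etc.).  Local Pearson correlation between a model surface and a
predictor layer in a moving window (21 cells by default) shows where a
predictor drives the response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: default corner/intermediate palette for a 3x3 bivariate legend,
#: indexed by (suitability class, connectivity class), low=0 .. high=2
DEFAULT_PALETTE_3X3 = {
    (0, 0): "#e8e8e8",
    (0, 1): "#ace4e4",
    (0, 2): "#5ac8c8",
    (1, 0): "#dfb0d6",
    (1, 1): "#a5add3",
    (1, 2): "#5698b9",
    (2, 0): "#be64ac",
    (2, 1): "#8c62aa",
    (2, 2): "#3b4994",
}

MASKED_CODE = -1


@dataclass
class BivariateMap:
    """Integer class raster plus its legend.

    ``classes`` holds ``suit_class * n_classes + conn_class`` per unmasked
    cell and :data:`MASKED_CODE` elsewhere.
    """

    classes: np.ndarray
    legend: pd.DataFrame  # columns: code, suit_class, conn_class, color
    n_classes: int


def scale01(layer: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1] over finite cells; NaN preserved."""
    layer = np.asarray(layer, dtype=float)
    vals = layer[np.isfinite(layer)]
    if vals.size == 0 or vals.max() == vals.min():
        raise ValueError("cannot scale a constant or empty layer")
    return (layer - vals.min()) / (vals.max() - vals.min())


def mask_low_suitability(suit: np.ndarray, threshold: float = 0.10) -> np.ndarray:
    """True where predicted probability of presence is below the threshold
    (strictly less than) or nodata; these cells are blanked in every map."""
    suit = np.asarray(suit, dtype=float)
    return ~np.isfinite(suit) | (suit < threshold)


def _quantile_classes(
    values: np.ndarray, valid: np.ndarray, n_classes: int
) -> np.ndarray:
    vals = values[valid]
    breaks = np.quantile(vals, np.arange(1, n_classes) / n_classes)
    if np.unique(breaks).size < breaks.size:
        logger.warning(
            "quantile breaks degenerate (too few distinct values); "
            "falling back to equal-interval breaks"
        )
        breaks = vals.min() + (vals.max() - vals.min()) * np.arange(
            1, n_classes
        ) / n_classes
    out = np.full(values.shape, MASKED_CODE, dtype=int)
    out[valid] = np.digitize(values[valid], breaks, right=True)
    return out


def bivariate_classify(
    suit: np.ndarray,
    conn: np.ndarray,
    n_classes: int = 3,
    masked: np.ndarray | None = None,
    palette: dict[tuple[int, int], str] | None = None,
) -> BivariateMap:
    """Joint quantile classification of two scaled surfaces.

    Each surface is cut independently into ``n_classes`` equal-count
    classes over unmasked cells, so marginal class sizes are balanced up
    to rounding; cells with identical values share a class.
    """
    suit = np.asarray(suit, dtype=float)
    conn = np.asarray(conn, dtype=float)
    if suit.shape != conn.shape:
        raise ValueError(f"layers not aligned: {suit.shape} vs {conn.shape}")
    valid = np.isfinite(suit) & np.isfinite(conn)
    if masked is not None:
        valid &= ~np.asarray(masked, dtype=bool)
    s_cls = _quantile_classes(suit, valid, n_classes)
    c_cls = _quantile_classes(conn, valid, n_classes)
    codes = np.full(suit.shape, MASKED_CODE, dtype=int)
    codes[valid] = s_cls[valid] * n_classes + c_cls[valid]

    if palette is None and n_classes == 3:
        palette = DEFAULT_PALETTE_3X3
    legend_rows = []
    for s in range(n_classes):
        for c in range(n_classes):
            legend_rows.append(
                {
                    "code": s * n_classes + c,
                    "suit_class": s,
                    "conn_class": c,
                    "color": (palette or {}).get((s, c), ""),
                }
            )
    return BivariateMap(
        classes=codes,
        legend=pd.DataFrame(legend_rows),
        n_classes=n_classes,
    )


def local_correlation(
    x: np.ndarray,
    y: np.ndarray,
    window: int = 21,
    masked: np.ndarray | None = None,
) -> np.ndarray:
    """Moving-window Pearson correlation of two layers.

    Per cell, r is computed over the ``window``x``window`` neighborhood
    restricted to valid cells; windows with fewer than 3 valid cells or
    zero variance in either layer yield NaN.  Implemented with box-filter
    sums, so the cost is independent of window size.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"layers not aligned: {x.shape} vs {y.shape}")
    valid = np.isfinite(x) & np.isfinite(y)
    if masked is not None:
        valid &= ~np.asarray(masked, dtype=bool)
    xf = np.where(valid, x, 0.0)
    yf = np.where(valid, y, 0.0)
    w2 = float(window * window)

    def boxsum(arr: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(arr, size=window, mode="constant") * w2

    n = boxsum(valid.astype(float))
    sx, sy = boxsum(xf), boxsum(yf)
    sxx, syy, sxy = boxsum(xf * xf), boxsum(yf * yf), boxsum(xf * yf)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        var_x = sxx - sx * sx / n
        var_y = syy - sy * sy / n
        r = cov / np.sqrt(var_x * var_y)
        # guard against box-filter round-off: variances are non-negative sums
        tol = 1e-9 * np.maximum(sxx + syy, 1.0) / n
    bad = (~valid) | (n < 3) | (var_x <= tol) | (var_y <= tol)
    r[bad] = np.nan
    return np.clip(r, -1.0, 1.0)
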