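"""Raster operations used by both the suitability and connectivity pipelines.

The landscape-genetic analysis needs a small set of raster primitives that
general GIS stacks bundle but that are worth having under direct control
here: supercover rasterization of straight site-to-site segments, medians of
layer values along those segments, a uniform-raster geographic distance (the
number of 1-km cells a path crosses), Gaussian kernel-density layers (river
density, sampling effort), seasonal bioclimatic variables from monthly
climate stacks, and per-pixel max/difference map algebra.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import GridSpec, RasterStack

logger = logging.getLogger(__name__)

# fraction of path cells that may be nodata before a (pair, layer) median is
# flagged missing instead of computed from the remainder
MAX_NODATA_FRACTION = 0.5


# --------------------------------------------------------------- rasterline


def rasterline_cells(
    a: tuple[float, float], b: tuple[float, float], grid: GridSpec
) -> list[tuple[int, int]]:
    """Cells crossed by the straight segment from a to b (supercover).

    Every cell the segment touches is included, so thin diagonal features
    cannot be skipped.  The first cell contains ``a``, the last contains
    ``b``, consecutive cells are 8-neighbors, no cell repeats, and
    ``rasterline_cells(b, a)`` is the exact reverse.
    """
    for name, (x, y) in (("a", a), ("b", b)):
        if not grid.contains(x, y):
            raise ValueError(f"endpoint {name}=({x}, {y}) outside grid extent")
    # canonical direction so reversal symmetry holds by construction
    if (b[0], b[1]) < (a[0], a[1]):
        return list(reversed(rasterline_cells(b, a, grid)))

    cs = grid.cell_size
    # grid-fraction coordinates: u east in cells, v south in cells
    u0 = (a[0] - grid.x_origin) / cs
    v0 = (grid.y_origin - a[1]) / cs
    u1 = (b[0] - grid.x_origin) / cs
    v1 = (grid.y_origin - b[1]) / cs

    def clamp(idx: int, n: int) -> int:
        return min(max(idx, 0), n - 1)

    col = clamp(int(math.floor(u0)), grid.n_cols)
    row = clamp(int(math.floor(v0)), grid.n_rows)
    col_end = clamp(int(math.floor(u1)), grid.n_cols)
    row_end = clamp(int(math.floor(v1)), grid.n_rows)

    du, dv = u1 - u0, v1 - v0
    step_c = 1 if du > 0 else -1
    step_r = 1 if dv > 0 else -1
    # parametric distance to the next vertical / horizontal cell boundary
    t_max_u = ((col + (step_c > 0)) - u0) / du if du != 0 else math.inf
    t_max_v = ((row + (step_r > 0)) - v0) / dv if dv != 0 else math.inf
    t_delta_u = abs(1.0 / du) if du != 0 else math.inf
    t_delta_v = abs(1.0 / dv) if dv != 0 else math.inf

    cells = [(row, col)]
    max_steps = 4 * (grid.n_rows + grid.n_cols) + 8
    for _ in range(max_steps):
        if (row, col) == (row_end, col_end):
            break
        if t_max_u < t_max_v:
            col += step_c
            t_max_u += t_delta_u
        elif t_max_v < t_max_u:
            row += step_r
            t_max_v += t_delta_v
        else:
            # exact corner crossing: include both side cells, then the diagonal
            cells.append((row, col + step_c))
            cells.append((row + step_r, col))
            col += step_c
            row += step_r
            t_max_u += t_delta_u
            t_max_v += t_delta_v
        cells.append((row, col))
    else:  # pragma: no cover - defensive
        raise RuntimeError("rasterline traversal did not terminate")
    return cells


# ------------------------------------------------------------ path medians


def path_summaries(
    stack: RasterStack,
    pairs: pd.DataFrame,
    layers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-layer medians along straight paths plus geographic distance.

    ``pairs`` needs columns x_a, y_a, x_b, y_b (any extra columns are kept).
    The geographic distance is the sum of an all-ones 1-km raster over the
    path cells, i.e. exactly the cell count.  Nodata cells are skipped in
    the median; if more than half the path is nodata for a layer the value
    is set to NaN and a warning is logged.
    """
    layers = list(layers) if layers is not None else stack.layer_names
    records = []
    n_flagged = 0
    for rec in pairs.itertuples(index=False):
        cells = rasterline_cells((rec.x_a, rec.y_a), (rec.x_b, rec.y_b), stack.grid)
        rows = np.array([c[0] for c in cells])
        cols = np.array([c[1] for c in cells])
        out = rec._asdict()
        out["geographic_distance"] = len(cells)
        for name in layers:
            vals = stack.values_at(name, rows, cols)
            ok = np.isfinite(vals)
            if ok.mean() < (1.0 - MAX_NODATA_FRACTION) or not ok.any():
                out[name] = np.nan
                n_flagged += 1
            else:
                out[name] = float(np.median(vals[ok]))
        records.append(out)
    if n_flagged:
        logger.warning("path_summaries: %d (pair, layer) medians flagged nodata", n_flagged)
    return pd.DataFrame.from_records(records)


# ------------------------------------------------------------------- KDE


def _discretize(geoms: Iterable, spacing: float) -> np.ndarray:
    """Flatten points / shapely geometries to an (n, 2) coordinate array.

    Line features are sampled at ``spacing`` intervals along their length so
    a line contributes kernel mass proportional to nothing but its sampled
    vertices (the conventional raster-KDE treatment of stream networks).
    """
    pts: list[tuple[float, float]] = []
    for g in geoms:
        if hasattr(g, "geom_type"):
            if g.geom_type == "Point":
                pts.append((g.x, g.y))
            elif g.geom_type in ("LineString", "LinearRing"):
                n = max(int(math.ceil(g.length / spacing)), 1)
                for i in range(n + 1):
                    p = g.interpolate(min(i * spacing, g.length))
                    pts.append((p.x, p.y))
            elif g.geom_type in ("MultiPoint", "MultiLineString", "GeometryCollection"):
                pts.extend(map(tuple, _discretize(list(g.geoms), spacing)))
            else:
                raise ValueError(f"unsupported geometry type {g.geom_type}")
        else:
            x, y = g
            pts.append((float(x), float(y)))
    return np.asarray(pts, dtype=float)


def kernel_density_raster(
    geoms: Sequence, bandwidth: float, grid: GridSpec
) -> np.ndarray:
    """Gaussian kernel density of points/lines evaluated at cell centers.

    Normalized so the layer integrates to ~1 over the plane; mass falling
    outside the grid extent is truncated, so the grid sum times cell area is
    slightly below 1 for features near edges.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    pts = _discretize(geoms, spacing=grid.cell_size)
    if pts.size == 0:
        raise ValueError("kernel_density_raster: empty geometry list")
    X, Y = grid.center_mesh()
    dens = np.zeros(grid.shape, dtype=float)
    two_h2 = 2.0 * bandwidth * bandwidth
    for x, y in pts:
        dens += np.exp(-((X - x) ** 2 + (Y - y) ** 2) / two_h2)
    dens /= len(pts) * 2.0 * math.pi * bandwidth * bandwidth
    return dens


# --------------------------------------------------------------- bioclim


def default_seasons() -> dict[str, list[int]]:
    """Standard rolling three-month quarters (Jan-Feb-Mar, Feb-Mar-Apr, ...)."""
    return {
        f"q{m:02d}": [m, m % 12 + 1, (m + 1) % 12 + 1] for m in range(1, 13)
    }


def compute_bioclim(
    tmin: Sequence[np.ndarray],
    tmax: Sequence[np.ndarray],
    prec: Sequence[np.ndarray],
    seasons: Mapping[str, Sequence[int]] | None = None,
) -> dict[str, np.ndarray]:
    """The 19 bioclimatic variables from monthly climate layers.

    Season-dependent variables (bio8-11, bio16-19) use the supplied named
    month windows instead of the default rolling quarters, so regions whose
    wet/dry seasons do not align with calendar quarters can be described by
    windows chosen from the local precipitation regime.  Per cell, the
    wettest/driest season maximizes/minimizes total precipitation and the
    warmest/coldest season maximizes/minimizes mean temperature; ties go to
    the first-listed season.  Standard deviations are sample SDs (ddof=1)
    and bio15 is 100*sd(prec+1)/mean(prec+1), following the convention of
    the classic biovars implementation.
    """
    for name, stack in (("tmin", tmin), ("tmax", tmax), ("prec", prec)):
        if len(stack) != 12:
            raise ValueError(f"{name}: expected 12 monthly layers, got {len(stack)}")
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    prec = np.asarray(prec, dtype=float)
    if seasons is None:
        seasons = default_seasons()
    for sname, months in seasons.items():
        if not months or any(m < 1 or m > 12 for m in months):
            raise ValueError(f"season {sname!r}: months must be in 1..12, got {months}")

    tavg = (tmin + tmax) / 2.0
    bio: dict[str, np.ndarray] = {}
    bio["bio01"] = tavg.mean(axis=0)
    bio["bio02"] = (tmax - tmin).mean(axis=0)
    bio["bio04"] = 100.0 * tavg.std(axis=0, ddof=1)
    bio["bio05"] = tmax.max(axis=0)
    bio["bio06"] = tmin.min(axis=0)
    bio["bio07"] = bio["bio05"] - bio["bio06"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bio["bio03"] = np.where(
            bio["bio07"] != 0, 100.0 * bio["bio02"] / bio["bio07"], np.nan
        )
    bio["bio12"] = prec.sum(axis=0)
    bio["bio13"] = prec.max(axis=0)
    bio["bio14"] = prec.min(axis=0)
    p1 = prec + 1.0
    bio["bio15"] = 100.0 * p1.std(axis=0, ddof=1) / p1.mean(axis=0)

    # season aggregates: (n_seasons, rows, cols)
    idx = [np.asarray(months, dtype=int) - 1 for months in seasons.values()]
    t_season = np.stack([tavg[i].mean(axis=0) for i in idx])
    p_season = np.stack([prec[i].sum(axis=0) for i in idx])

    def pick(agg: np.ndarray, which: np.ndarray) -> np.ndarray:
        return np.take_along_axis(agg, which[None], axis=0)[0]

    wettest = p_season.argmax(axis=0)
    driest = p_season.argmin(axis=0)
    warmest = t_season.argmax(axis=0)
    coldest = t_season.argmin(axis=0)
    bio["bio08"] = pick(t_season, wettest)
    bio["bio09"] = pick(t_season, driest)
    bio["bio10"] = pick(t_season, warmest)
    bio["bio11"] = pick(t_season, coldest)
    bio["bio16"] = pick(p_season, wettest)
    bio["bio17"] = pick(p_season, driest)
    bio["bio18"] = pick(p_season, warmest)
    bio["bio19"] = pick(p_season, coldest)
    return {k: bio[k] for k in sorted(bio)}


# ------------------------------------------------------------ map algebra


def _aligned(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"layers not aligned: {a.shape} vs {b.shape}")
    return a, b


def combine_max(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel maximum; where one layer is nodata the other wins.

    The conservative way to merge a freshly modeled suitability surface
    with a prior map: over-predicting presence is the safe error for
    vector-control planning.
    """
    a, b = _aligned(a, b)
    return np.where(np.isnan(a), b, np.where(np.isnan(b), a, np.maximum(a, b)))


def change_map(future: np.ndarray, present: np.ndarray) -> np.ndarray:
    """future - present per pixel; nodata propagates."""
    future, present = _aligned(future, present)
    return future - present


# ------------------------------------------------------- moving statistics


def neighbor_correlation(arr: np.ndarray) -> float:
    """Lag-1 spatial autocorrelation: Pearson r of horizontally and
    vertically adjacent cell pairs (a quick Moran-style diagnostic)."""
    arr = np.asarray(arr, dtype=float)
    pairs_a = np.concatenate([arr[:, :-1].ravel(), arr[:-1, :].ravel()])
    pairs_b = np.concatenate([arr[:, 1:].ravel(), arr[1:, :].ravel()])
    ok = np.isfinite(pairs_a) & np.isfinite(pairs_b)
    return float(np.corrcoef(pairs_a[ok], pairs_b[ok])[0, 1])
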