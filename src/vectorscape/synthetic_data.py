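"""Truth-known synthetic landscapes, sampling sites, genotypes and presences.

The generator emulates the statistical structure the downstream models
assume, at desk scale:

* spatially autocorrelated, standardized environmental layers (smoothed
  Gaussian noise), mutually independent in expectation;
* two clusters of sampling sites on opposite halves of the grid (the
  east/west split of the study system), with latent per-site allele
  frequencies built so that expected chord distance between two sites
  grows linearly with the environmental cost of the straight path between
  them (isolation by resistance);
* microsatellite-style genotypes drawn from the latent site frequencies,
  with a little completely-at-random missingness;
* presence points drawn with probability proportional to a logistic
  function of weighted driver layers (the true suitability surface).

Because the drivers, weights and divergence rate are recorded in
:class:`SyntheticTruth`, every downstream model can be scored against the
generating process (does the forest recover the driver? does observed LOO
error beat the shuffled null?).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import geo
from .raster import GridSpec, RasterStack

MISSING_FRACTION = 0.02  # MCAR genotype calls

#: inter-cluster latent divergence (chord-distance units) standing in for the
#: deep split the within-cluster analysis deliberately excludes
CLUSTER_SPLIT_CSE = 0.5


@dataclass
class SyntheticTruth:
    """Generating parameters shared across the synthetic modules.

    divergence_rate is in chord-distance units per unit path cost, where
    path cost is the sum of exp(weighted driver values) over the cells of
    the straight path between two sites (a log-linear resistance surface,
    so costs are positive and standardized layers act multiplicatively).
    """

    driver_layer_names: list[str] = field(
        default_factory=lambda: ["env01", "env02"]
    )
    suitability_coefficients: dict[str, float] = field(
        default_factory=lambda: {"env01": 8.0}
    )
    resistance_coefficients: dict[str, float] = field(
        default_factory=lambda: {"env02": 1.0}
    )
    divergence_rate: float = 0.002
    seed: int = 0
    suitability_intercept: float = -12.0

    def __post_init__(self) -> None:
        if self.divergence_rate < 0:
            raise ValueError("divergence_rate must be non-negative")
        for coefs in (self.suitability_coefficients, self.resistance_coefficients):
            unknown = set(coefs) - set(self.driver_layer_names)
            if unknown:
                raise ValueError(
                    f"coefficients reference non-driver layers: {sorted(unknown)}"
                )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ------------------------------------------------------------- landscape


def gen_landscape(
    n_layers: int,
    n_rows: int,
    n_cols: int,
    corr_length: float,
    seed: int,
    nodata_fraction: float = 0.0,
    cell_size: float = 1.0,
    crs: str = "synthetic-km",
) -> RasterStack:
    """Independent spatially autocorrelated layers, standardized to zero
    mean and unit variance over unmasked cells.

    Each layer is white noise smoothed with a Gaussian filter of scale
    ``corr_length`` (in cells).  An optional nodata blob (the "ocean") is
    carved out where an extra smooth field falls below its
    ``nodata_fraction`` quantile.
    """
    if n_layers < 2:
        raise ValueError(f"need at least 2 layers, got {n_layers}")
    if n_rows < 20 or n_cols < 20:
        raise ValueError(f"grid must be at least 20x20, got {n_rows}x{n_cols}")
    if corr_length < 1:
        raise ValueError(f"corr_length must be >= 1 cell, got {corr_length}")
    if not 0 <= nodata_fraction < 1:
        raise ValueError("nodata_fraction must be in [0, 1)")

    rng = np.random.default_rng(seed)
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=0.0,
        y_origin=n_rows * cell_size,
        cell_size=cell_size,
        crs=crs,
    )
    mask = np.ones((n_rows, n_cols), dtype=bool)
    if nodata_fraction > 0:
        blob = ndimage.gaussian_filter(
            rng.standard_normal((n_rows, n_cols)), sigma=max(corr_length, 3)
        )
        mask = blob > np.quantile(blob, nodata_fraction)
    stack = RasterStack(grid=grid, mask=mask)
    for i in range(n_layers):
        raw = ndimage.gaussian_filter(
            rng.standard_normal((n_rows, n_cols)), sigma=corr_length
        )
        vals = raw[mask]
        layer = (raw - vals.mean()) / vals.std()
        stack.add_layer(f"env{i + 1:02d}", layer)
    return stack


# -------------------------------------------------- truth-derived surfaces


def _weighted_sum(stack: RasterStack, coefs: dict[str, float]) -> np.ndarray:
    out = np.zeros(stack.grid.shape)
    for name, w in coefs.items():
        out += w * stack[name]
    return out


def suitability_probability(stack: RasterStack, truth: SyntheticTruth) -> np.ndarray:
    """True per-cell presence probability: logistic in the driver layers."""
    z = truth.suitability_intercept + _weighted_sum(
        stack, truth.suitability_coefficients
    )
    return 1.0 / (1.0 + np.exp(-z))


def resistance_surface(stack: RasterStack, truth: SyntheticTruth) -> np.ndarray:
    """Per-cell movement cost: exp(weighted driver values), always positive."""
    return np.exp(_weighted_sum(stack, truth.resistance_coefficients))


def path_cost(
    stack: RasterStack,
    truth: SyntheticTruth,
    a: tuple[float, float],
    b: tuple[float, float],
) -> float:
    """Sum of resistance over the supercover cells of the straight path."""
    res = resistance_surface(stack, truth)
    cells = geo.rasterline_cells(a, b, stack.grid)
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    return float(res[rows, cols].sum())


def _pairwise_costs(
    stack: RasterStack, truth: SyntheticTruth, coords: np.ndarray
) -> np.ndarray:
    res = resistance_surface(stack, truth)
    n = len(coords)
    cost = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cells = geo.rasterline_cells(tuple(coords[i]), tuple(coords[j]), stack.grid)
            rows = np.array([c[0] for c in cells])
            cols = np.array([c[1] for c in cells])
            cost[i, j] = cost[j, i] = res[rows, cols].sum()
    return cost


# ------------------------------------------------------ sites & genotypes


def _classical_mds(d: np.ndarray) -> np.ndarray:
    """Embed a target distance matrix in Euclidean space (negative
    eigenvalues clipped); returns (n, k) coordinates."""
    n = d.shape[0]
    if n == 1:
        return np.zeros((1, 1))
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    keep = w > max(w.max(), 0) * 1e-10
    if not keep.any():
        return np.zeros((n, 1))
    return v[:, keep] * np.sqrt(w[keep])


def _place_sites(
    stack: RasterStack, n_sites_per_cluster: tuple[int, int], rng: np.random.Generator
) -> pd.DataFrame:
    """Random distinct unmasked cells; clusters on opposite grid halves so
    within-cluster straight paths never cross the other cluster's range."""
    grid = stack.grid
    half = grid.n_cols // 2
    rows_all, cols_all = np.nonzero(stack.mask)
    records = []
    for label, n_sites, col_ok in (
        ("west", n_sites_per_cluster[0], cols_all < half),
        ("east", n_sites_per_cluster[1], cols_all >= half),
    ):
        rows, cols = rows_all[col_ok], cols_all[col_ok]
        if n_sites > len(rows):
            raise ValueError(
                f"cluster {label!r}: {n_sites} sites requested but only "
                f"{len(rows)} unmasked cells available"
            )
        pick = rng.choice(len(rows), size=n_sites, replace=False)
        for k, idx in enumerate(sorted(pick)):
            x, y = grid.cell_center(rows[idx], cols[idx])
            records.append(
                {
                    "site_id": f"{label[0].upper()}{k + 1:02d}",
                    "x": x,
                    "y": y,
                    "row": int(rows[idx]),
                    "col": int(cols[idx]),
                    "cluster": label,
                }
            )
    return pd.DataFrame(records)


def latent_site_frequencies(
    stack: RasterStack,
    sites: pd.DataFrame,
    n_loci: int,
    n_alleles: int,
    truth: SyntheticTruth,
) -> dict[tuple, np.ndarray]:
    """Noise-free per-(site, locus) allele-frequency vectors.

    Sites are embedded so their latent Euclidean separation approximates
    divergence_rate * path_cost; each locus perturbs a shared ancestral
    Dirichlet frequency vector along random sum-zero directions scaled by
    the embedding coordinates.  The directions are normalized in the
    chord-distance metric (sum u^2 / ancestral = pi^2) so that, at small
    divergence, expected chord distance is approximately the embedding
    distance itself — i.e. approximately linear in path cost.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 7]))
    clusters = sorted(sites["cluster"].unique())
    # per-cluster embeddings in disjoint coordinate blocks + one split axis
    blocks: list[np.ndarray] = []
    for cl in clusters:
        sub = sites[sites["cluster"] == cl]
        coords = sub[["x", "y"]].to_numpy()
        cost = _pairwise_costs(stack, truth, coords)
        blocks.append(_classical_mds(truth.divergence_rate * cost))
    dims = [b.shape[1] for b in blocks]
    total = sum(dims) + 1
    z = np.zeros((len(sites), total))
    offset = 0
    for cl, block, d in zip(clusters, blocks, dims):
        sel = (sites["cluster"] == cl).to_numpy()
        z[sel, offset : offset + d] = block
        offset += d
    if len(clusters) > 1 and truth.divergence_rate > 0:
        # ancient vicariance between clusters; at rate 0 the gene pool is
        # fully homogeneous (the no-divergence limit)
        z[(sites["cluster"] == clusters[-1]).to_numpy(), -1] = CLUSTER_SPLIT_CSE

    freqs: dict[tuple, np.ndarray] = {}
    for l in range(n_loci):
        locus = f"loc{l + 1:02d}"
        ancestral = rng.dirichlet(np.full(n_alleles, 2.0))
        u = rng.standard_normal((total, n_alleles))
        u -= u.mean(axis=1, keepdims=True)
        norm = np.sqrt((u**2 / ancestral).sum(axis=1))
        u *= np.pi / norm[:, None]
        for i, site_id in enumerate(sites["site_id"]):
            p = ancestral + z[i] @ u
            p = np.clip(p, 1e-4, None)
            freqs[(site_id, locus)] = p / p.sum()
    return freqs


def gen_sites_and_genotypes(
    stack: RasterStack,
    truth: SyntheticTruth,
    n_sites_per_cluster: tuple[int, int] = (16, 13),
    n_ind_per_site: int = 23,
    n_loci: int = 11,
    n_alleles: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sampling sites plus long-format genotypes drawn from the latent
    site frequencies (two independent allele draws per locus, ~2% of calls
    missing completely at random)."""
    if n_alleles < 2:
        raise ValueError("need at least 2 alleles per locus")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 11]))
    sites = _place_sites(stack, n_sites_per_cluster, rng)
    freqs = latent_site_frequencies(stack, sites, n_loci, n_alleles, truth)
    allele_labels = [f"a{k + 1}" for k in range(n_alleles)]
    loci = [f"loc{l + 1:02d}" for l in range(n_loci)]

    rows = []
    for rec in sites.itertuples(index=False):
        for i in range(n_ind_per_site):
            ind = f"{rec.site_id}_i{i + 1:03d}"
            for locus in loci:
                p = freqs[(rec.site_id, locus)]
                if rng.random() < MISSING_FRACTION:
                    a = b = pd.NA
                else:
                    draw = rng.choice(n_alleles, size=2, p=p)
                    a, b = allele_labels[draw[0]], allele_labels[draw[1]]
                rows.append(
                    {
                        "individual": ind,
                        "site": rec.site_id,
                        "cluster": rec.cluster,
                        "locus": locus,
                        "allele_a": a,
                        "allele_b": b,
                    }
                )
    genotypes = pd.DataFrame(rows)
    return sites, genotypes


# ------------------------------------------------------------- presences


def gen_presence(
    stack: RasterStack,
    truth: SyntheticTruth,
    n_points: int,
    seed: int,
) -> pd.DataFrame:
    """Presence points: one unmasked cell each, sampled without replacement
    with probability proportional to the true suitability surface."""
    if n_points < 30:
        raise ValueError(f"need at least 30 presence points, got {n_points}")
    prob = suitability_probability(stack, truth)
    rows, cols = np.nonzero(stack.mask)
    p = prob[rows, cols]
    eligible = p > 1e-9
    if n_points > eligible.sum():
        raise ValueError(
            f"{n_points} points requested but only {int(eligible.sum())} cells "
            "have non-negligible suitability"
        )
    rows, cols, p = rows[eligible], cols[eligible], p[eligible]
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n_points, replace=False, p=p / p.sum())
    pick = np.sort(pick)
    xy = np.array([stack.grid.cell_center(r, c) for r, c in zip(rows[pick], cols[pick])])
    return pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "row": rows[pick],
            "col": cols[pick],
        }
    )
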