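"""Allele frequencies, Cavalli-Sforza & Edwards chord distances, Mantel tests.

Genotypes are held in long format: one row per (individual, locus) with two
allele calls.  A locus call is either fully present or fully missing.  Site
allele frequencies are simple counts over non-missing calls; the allele
support of a locus is the union of alleles observed at any site, so
frequency vectors are directly comparable between sites (an allele unseen
at a site has frequency 0 and contributes nothing to the chord overlap).

The chord distance between two sites at one locus is the angular distance
between their allele-frequency vectors mapped to the unit sphere by the
square-root transform:

    cos(theta_l) = sum_a sqrt(p_la * q_la)
    D_l = (2/pi) * sqrt(2 * (1 - cos(theta_l)))

The multilocus distance is the mean of D_l over loci genotyped in both
sites (pairwise deletion, which is why chord distance behaves well with
missing microsatellite data).  A pooled variant,
(2/pi)*sqrt(2*(1 - mean_l cos(theta_l))), is available for comparison with
implementations that aggregate before the square root.  Note the averaged
chord distance is not guaranteed to satisfy the triangle inequality.
"""

from __future__ import annotations

import itertools
import math
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel

GENOTYPE_COLUMNS = ["individual", "site", "cluster", "locus", "allele_a", "allele_b"]

CSEVariant = Literal["mean_chord", "pooled"]

#: single-locus maximum: disjoint allele sets, cos(theta) = 0
CSE_MAX = (2.0 / math.pi) * math.sqrt(2.0)


def validate_genotypes(g: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in GENOTYPE_COLUMNS if c not in g.columns]
    if missing_cols:
        raise ValueError(f"genotype table missing columns {missing_cols}")
    site_map = g.groupby("individual")["site"].nunique()
    if (site_map > 1).any():
        bad = site_map[site_map > 1].index.tolist()
        raise ValueError(f"individuals mapped to multiple sites: {bad}")
    cluster_map = g.groupby("site")["cluster"].nunique()
    if (cluster_map > 1).any():
        bad = cluster_map[cluster_map > 1].index.tolist()
        raise ValueError(f"sites mapped to multiple clusters: {bad}")
    half = g["allele_a"].isna() != g["allele_b"].isna()
    if half.any():
        raise ValueError(
            f"{int(half.sum())} locus calls are half-missing; a call must be "
            "fully present or fully missing"
        )
    return g


class FreqTable:
    """Per-site, per-locus allele-frequency vectors on a shared support."""

    def __init__(
        self,
        support: dict[str, list],
        freqs: dict[tuple, np.ndarray],
        n_obs: dict[tuple, int],
        site_cluster: dict,
    ):
        self.support = support
        self._freqs = freqs
        self._n_obs = n_obs
        self.site_cluster = site_cluster

    @property
    def sites(self) -> list:
        return sorted(self.site_cluster)

    @property
    def loci(self) -> list:
        return sorted(self.support)

    def freq(self, site, locus) -> np.ndarray | None:
        """Frequency vector over the locus support, or None if the site has
        no non-missing calls at that locus."""
        return self._freqs.get((site, locus))

    def n_obs(self, site, locus) -> int:
        return self._n_obs.get((site, locus), 0)

    def site_vectors(self, site) -> dict[str, np.ndarray]:
        return {
            loc: self._freqs[(site, loc)]
            for loc in self.loci
            if (site, loc) in self._freqs
        }


def allele_frequencies(g: pd.DataFrame) -> FreqTable:
    """Observed allele frequencies per site and locus.

    The denominator is the number of non-missing allele calls (twice the
    number of fully genotyped individuals at that site and locus).
    """
    g = validate_genotypes(g)
    calls = g.dropna(subset=["allele_a"])
    long = pd.concat(
        [
            calls[["site", "locus", "allele_a"]].rename(columns={"allele_a": "allele"}),
            calls[["site", "locus", "allele_b"]].rename(columns={"allele_b": "allele"}),
        ]
    )
    support = {
        locus: sorted(sub["allele"].unique())
        for locus, sub in long.groupby("locus")
    }
    counts = long.groupby(["site", "locus", "allele"]).size()

    sites_with_data = set(calls["site"].unique())
    all_sites = set(g["site"].unique())
    empty = sorted(all_sites - sites_with_data)
    if empty:
        raise ValueError(
            f"site(s) {empty} have zero non-missing calls at every locus"
        )

    freqs: dict[tuple, np.ndarray] = {}
    n_obs: dict[tuple, int] = {}
    for (site, locus), sub in counts.groupby(level=[0, 1]):
        alleles = support[locus]
        vec = np.zeros(len(alleles))
        sub = sub.droplevel([0, 1])
        total = int(sub.sum())
        for i, a in enumerate(alleles):
            vec[i] = sub.get(a, 0)
        freqs[(site, locus)] = vec / total
        n_obs[(site, locus)] = total
    site_cluster = g.drop_duplicates("site").set_index("site")["cluster"].to_dict()
    return FreqTable(support, freqs, n_obs, site_cluster)


def cse_distance(
    p: Mapping[str, np.ndarray],
    q: Mapping[str, np.ndarray],
    variant: CSEVariant = "mean_chord",
) -> float:
    """Chord distance between two sites from per-locus frequency vectors.

    ``p`` and ``q`` map locus -> frequency vector on the same support; loci
    missing from either side are dropped (pairwise deletion).
    """
    shared = sorted(set(p) & set(q))
    if not shared:
        raise ValueError("no shared non-missing locus between the two sites")
    cosines = []
    for locus in shared:
        pv, qv = np.asarray(p[locus]), np.asarray(q[locus])
        if pv.shape != qv.shape:
            raise ValueError(
                f"locus {locus!r}: frequency vectors on different supports "
                f"({pv.shape} vs {qv.shape})"
            )
        cosines.append(min(float(np.sqrt(pv * qv).sum()), 1.0))
    cosines = np.array(cosines)
    if variant == "mean_chord":
        return float(np.mean((2.0 / math.pi) * np.sqrt(2.0 * (1.0 - cosines))))
    elif variant == "pooled":
        return float((2.0 / math.pi) * math.sqrt(2.0 * (1.0 - cosines.mean())))
    raise ValueError(f"unknown CSE variant {variant!r}")


def pairwise_cse(
    g: pd.DataFrame, variant: CSEVariant = "mean_chord"
) -> pd.DataFrame:
    """CSE distances for all unordered within-cluster site pairs.

    Cross-cluster pairs are deliberately absent: between-cluster divergence
    reflects old vicariance (the Rift split in the tsetse system), not the
    contemporary landscape the connectivity model is after.  For cluster
    sizes a and b the table has a(a-1)/2 + b(b-1)/2 rows.
    """
    ft = allele_frequencies(g)
    rows = []
    by_cluster: dict = {}
    for site, cluster in ft.site_cluster.items():
        by_cluster.setdefault(cluster, []).append(site)
    for cluster in sorted(by_cluster, key=str):
        sites = sorted(by_cluster[cluster], key=str)
        vecs = {s: ft.site_vectors(s) for s in sites}
        for sa, sb in itertools.combinations(sites, 2):
            rows.append(
                {
                    "site_a": sa,
                    "site_b": sb,
                    "cluster": cluster,
                    "cse": cse_distance(vecs[sa], vecs[sb], variant=variant),
                }
            )
    return pd.DataFrame(rows, columns=["site_a", "site_b", "cluster", "cse"])


def distance_matrix(dists: pd.DataFrame, sites: list | None = None) -> pd.DataFrame:
    """Square symmetric matrix from the edge list (NaN where no pair)."""
    if sites is None:
        sites = sorted(set(dists["site_a"]) | set(dists["site_b"]), key=str)
    mat = pd.DataFrame(np.nan, index=sites, columns=sites)
    np.fill_diagonal(mat.values, 0.0)
    for rec in dists.itertuples(index=False):
        mat.loc[rec.site_a, rec.site_b] = rec.cse
        mat.loc[rec.site_b, rec.site_a] = rec.cse
    return mat


def mantel_test(
    dA: np.ndarray | pd.DataFrame,
    dB: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; the
    one-sided p-value is (1 + #{permuted r >= observed}) / (n_perm + 1)
    under joint row/column permutations of ``dB``.
    """
    dA = np.asarray(dA, dtype=float)
    dB = np.asarray(dB, dtype=float)
    if dA.shape != dB.shape or dA.ndim != 2 or dA.shape[0] != dA.shape[1]:
        raise ValueError(f"distance matrices mismatched: {dA.shape} vs {dB.shape}")
    r, p, _ = _skbio_mantel(
        DistanceMatrix(dA),
        DistanceMatrix(dB),
        method="pearson",
        permutations=n_perm,
        alternative="greater",
        seed=seed,
    )
    return float(r), float(p)


def validate_site_extent(traps: pd.DataFrame, max_extent: float = 2.0) -> None:
    """Check that all traps within a sampling site lie within ``max_extent``
    of each other (km on a projected grid).

    Sites wider than this should have been split upstream during data
    curation (a "site" is meant to be a point on a 1-km grid); this
    validator flags violations but performs no re-splitting.
    """
    bad = []
    for site, sub in traps.groupby("site"):
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
        if d.max() > max_extent:
            bad.append((site, float(d.max())))
    if bad:
        detail = ", ".join(f"{s} ({d:.2f})" for s, d in bad)
        raise ValueError(
            f"site(s) exceed the {max_extent} km within-site extent: {detail}"
        )


# ------------------------------------------------------------------- I/O


def write_genotypes_csv(g: pd.DataFrame, path) -> None:
    g.to_csv(path, index=False)


def read_genotypes_csv(path) -> pd.DataFrame:
    g = pd.read_csv(path, dtype={"allele_a": "string", "allele_b": "string"})
    return validate_genotypes(g)


def write_genepop(g: pd.DataFrame, path, title: str = "vectorscape export") -> None:
    """Genepop export with 3-digit numeric allele codes (000 = missing)."""
    g = validate_genotypes(g)
    loci = sorted(g["locus"].unique())
    codes: dict[str, dict] = {}
    for locus in loci:
        alleles = sorted(
            set(g.loc[g["locus"] == locus, "allele_a"].dropna())
            | set(g.loc[g["locus"] == locus, "allele_b"].dropna())
        )
        codes[locus] = {a: f"{i + 1:03d}" for i, a in enumerate(alleles)}
    lines = [title]
    lines.extend(str(locus) for locus in loci)
    wide = g.set_index(["individual", "locus"])
    for site, sub in g.groupby("site", sort=True):
        lines.append("Pop")
        for ind in sorted(sub["individual"].unique()):
            parts = []
            for locus in loci:
                try:
                    rec = wide.loc[(ind, locus)]
                    a, b = rec["allele_a"], rec["allele_b"]
                except KeyError:
                    a = b = None
                if pd.isna(a):
                    parts.append("000000")
                else:
                    parts.append(codes[locus][a] + codes[locus][b])
            lines.append(f"{ind} ,  " + " ".join(parts))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genepop(path, site_names: list[str] | None = None) -> pd.DataFrame:
    """Minimal Genepop reader (2- or 3-digit codes; cluster left empty)."""
    with open(path) as fh:
        raw = [line.rstrip("\n") for line in fh]
    loci: list[str] = []
    i = 1
    while i < len(raw) and raw[i].strip().lower() != "pop":
        loci.extend(s.strip() for s in raw[i].split(",") if s.strip())
        i += 1
    rows = []
    pop_idx = -1
    for line in raw[i:]:
        if line.strip().lower() == "pop":
            pop_idx += 1
            continue
        if not line.strip():
            continue
        ind, _, genos = line.partition(",")
        alleles = genos.split()
        if len(alleles) != len(loci):
            raise ValueError(f"individual {ind.strip()!r}: expected {len(loci)} loci")
        site = (
            site_names[pop_idx]
            if site_names is not None
            else f"pop{pop_idx + 1:02d}"
        )
        for locus, code in zip(loci, alleles):
            width = len(code) // 2
            a, b = code[:width], code[width:]
            missing = set(a) == {"0"} or set(b) == {"0"}
            rows.append(
                {
                    "individual": ind.strip(),
                    "site": site,
                    "cluster": pd.NA,
                    "locus": locus,
                    "allele_a": pd.NA if missing else a,
                    "allele_b": pd.NA if missing else b,
                }
            )
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
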