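import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vectorscape import synthetic_data

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")
from vectorscape.raster import GridSpec, RasterStack


@pytest.fixture(scope="session")
def small_stack() -> RasterStack:
    """Four autocorrelated layers on a 40x50 grid, no nodata."""
    return synthetic_data.gen_landscape(
        n_layers=4, n_rows=40, n_cols=50, corr_length=3, seed=7
    )


@pytest.fixture(scope="session")
def masked_stack() -> RasterStack:
    """Landscape with a ~10% nodata blob."""
    return synthetic_data.gen_landscape(
        n_layers=4, n_rows=40, n_cols=50, corr_length=3, seed=7,
        nodata_fraction=0.10,
    )


@pytest.fixture
def plain_grid() -> GridSpec:
    return GridSpec(n_rows=20, n_cols=30, x_origin=0.0, y_origin=20.0, cell_size=1.0)


def make_genotypes(rows: list[tuple]) -> pd.DataFrame:
    """Rows of (individual, site, cluster, locus, allele_a, allele_b)."""
    df = pd.DataFrame(
        rows,
        columns=["individual", "site", "cluster", "locus", "allele_a", "allele_b"],
    )
    return df.astype(
        {"allele_a": "object", "allele_b": "object"}
    ).replace({None: pd.NA})


def genotypes_from_freqs(
    site_freqs: dict[str, np.ndarray],
    n_ind: int,
    seed: int = 0,
    locus: str = "loc01",
    cluster: str = "c1",
) -> pd.DataFrame:
    """Single-locus genotypes drawn from known per-site allele frequencies."""
    rng = np.random.default_rng(seed)
    rows = []
    for site, p in site_freqs.items():
        labels = [f"a{k + 1}" for k in range(len(p))]
        for i in range(n_ind):
            a, b = rng.choice(len(p), size=2, p=p)
            rows.append(
                (f"{site}_i{i}", site, cluster, locus, labels[a], labels[b])
            )
    return make_genotypes(rows)
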