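import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from lesionkit.io_formats import NORMALIZED_LOG, RAW, CountMatrix, SpotTable


def make_counts(values, gene_ids=None, obs_ids=None, obs_meta=None, layer=RAW):
    """Build a CountMatrix from a dense (genes x obs) array."""
    values = np.asarray(values)
    n_genes, n_obs = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if obs_ids is None:
        obs_ids = [f"o{i}" for i in range(n_obs)]
    meta = pd.DataFrame(obs_meta) if obs_meta is not None else pd.DataFrame()
    return CountMatrix(values=sp.csr_matrix(values),
                       gene_ids=np.array(gene_ids, dtype=object),
                       obs_ids=np.array(obs_ids, dtype=object),
                       obs_meta=meta, layer_flag=layer)


def make_norm(values, **kw):
    return make_counts(values, layer=NORMALIZED_LOG, **kw)


def make_spots(coords, barcodes=None, clusters=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if barcodes is None:
        barcodes = [f"s{i}" for i in range(n)]
    df = pd.DataFrame({"barcode": barcodes, "x_um": coords[:, 0],
                       "y_um": coords[:, 1], "in_tissue": True})
    if clusters is not None:
        df["cluster"] = clusters
    return SpotTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_raw():
    """4 genes x 5 obs raw matrix with simple structure."""
    vals = np.array([
        [5, 0, 2, 1, 3],
        [0, 1, 0, 4, 2],
        [7, 3, 1, 0, 0],
        [2, 2, 2, 2, 2],
    ])
    return make_counts(vals)
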