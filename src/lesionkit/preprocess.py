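"""QC, normalization, feature selection, clustering, and gene-set scoring."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError
from .io_formats import NORMALIZED_LOG, RAW, CountMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Per-observation quality gates; bounds are inclusive and optional."""

    min_reads: Optional[float] = None
    max_reads: Optional[float] = None
    min_genes: Optional[int] = None
    max_mito_fraction: Optional[float] = None
    mito_gene_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.max_mito_fraction is not None and not 0 <= self.max_mito_fraction <= 1:
            raise ValidationError("max_mito_fraction must be in [0, 1]")
        if (self.min_reads is not None and self.max_reads is not None
                and self.min_reads > self.max_reads):
            raise ValidationError("min_reads > max_reads")


@dataclass
class ClusterLabels:
    labels: Dict[str, int]  # obs_id -> contiguous cluster label from 0
    k: int
    n_pcs: int
    resolution: float
    seed: int

    def as_series(self, obs_ids: Sequence[str]) -> pd.Series:
        return pd.Series([self.labels[o] for o in obs_ids], index=list(obs_ids))


@dataclass
class GeneScore:
    scores: pd.Series  # obs_id -> score
    set_name: str
    n_bins: int
    ctrl_size: int
    seed: int


# ---------------------------------------------------------------------------


def qc_filter(counts: CountMatrix, thresholds: QCThresholds) -> CountMatrix:
    """Drop observations failing read/gene/mitochondrial gates (inclusive bounds)."""
    if counts.layer_flag != RAW:
        raise ValidationError("qc_filter operates on the raw layer")
    reads = counts.counts_per_obs()
    keep = np.ones(counts.n_obs, dtype=bool)
    if thresholds.min_reads is not None:
        keep &= reads >= thresholds.min_reads
    if thresholds.max_reads is not None:
        keep &= reads <= thresholds.max_reads
    if thresholds.min_genes is not None:
        keep &= counts.genes_detected_per_obs() >= thresholds.min_genes
    if thresholds.max_mito_fraction is not None:
        mito = np.array([str(g).startswith(thresholds.mito_gene_prefix)
                         for g in counts.gene_ids])
        mito_reads = np.asarray(counts.values[mito, :].sum(axis=0)).ravel() if mito.any() \
            else np.zeros(counts.n_obs)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(reads > 0, mito_reads / np.maximum(reads, 1), 1.0)
        keep &= frac <= thresholds.max_mito_fraction
    if not keep.any():
        raise ValidationError("all observations filtered by QC thresholds")
    logger.info("qc_filter removed %d of %d observations",
                int((~keep).sum()), counts.n_obs)
    return counts.subset_obs(keep)


def normalize_log_cpm(counts: CountMatrix, target: float = 10000.0) -> CountMatrix:
    """Scale each observation to ``target`` total, then apply log(1 + x)."""
    if target <= 0:
        raise ValidationError("target must be > 0")
    totals = counts.counts_per_obs()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"zero-total observation(s): {list(counts.obs_ids[zero[:5]])}")
    mat = counts.values.tocsc(copy=True).astype(float)
    mat = mat.multiply(target / totals[None, :]).tocsr()
    mat.data = np.log1p(mat.data)
    return counts.with_values(mat, layer_flag=NORMALIZED_LOG)


def select_hvg(norm: CountMatrix, n: int, n_mean_bins: int = 20) -> List[str]:
    """Top-n genes by binned robust dispersion z-score (median/MAD per mean bin)."""
    if n <= 0:
        raise ValidationError("n must be > 0")
    if norm.layer_flag != NORMALIZED_LOG:
        raise ValidationError("select_hvg expects a log-normalized matrix")
    x = np.expm1(norm.dense())  # genes x obs, de-logged
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    df = pd.DataFrame({"gene": norm.gene_ids, "mean": mean, "disp": disp})
    finite = df["disp"].notna() & np.isfinite(df["disp"]) & (df["disp"] > 0)
    dff = df[finite].copy()
    if len(dff) == 0:
        raise ValidationError("no gene has a finite dispersion")
    n_bins = min(n_mean_bins, max(1, len(dff) // 2))
    ranks = dff["mean"].rank(method="first")
    dff["bin"] = pd.cut(ranks, bins=n_bins, labels=False)
    z = np.full(len(dff), np.nan)
    for b, idx in dff.groupby("bin").groups.items():
        vals = dff.loc[idx, "disp"].to_numpy()
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        loc = dff.index.get_indexer(idx)
        if mad == 0:
            z[loc] = 0.0
        else:
            z[loc] = (vals - med) / mad
    dff["z"] = z
    dff = dff.sort_values(["z", "gene"], ascending=[False, True], kind="mergesort")
    return list(dff["gene"].head(n))


def cluster_graph(norm: CountMatrix, genes: Sequence[str], k: int = 15,
                  n_pcs: int = 50, resolution: float = 1.0,
                  seed: int = 0) -> ClusterLabels:
    """Leiden community detection on a kNN graph of PCA-reduced, scaled genes."""
    if k >= norm.n_obs:
        raise ValidationError(f"k={k} must be < n_obs={norm.n_obs}")
    idx = norm.gene_index(genes)
    x = np.asarray(norm.values[idx, :].todense(), dtype=float).T  # obs x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x = np.clip((x - mu) / sd, -10.0, 10.0)
    n_comp = min(n_pcs, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    emb = pca.fit_transform(x)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, nbrs = nn.kneighbors(emb)
    edges = set()
    for i in range(len(emb)):
        for j in nbrs[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=len(emb), edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=-1)
    raw = np.array(part.membership)
    # relabel contiguous from 0, largest cluster first (ties by first member)
    sizes = pd.Series(raw).value_counts()
    first = {c: int(np.flatnonzero(raw == c)[0]) for c in sizes.index}
    order = sorted(sizes.index, key=lambda c: (-sizes[c], first[c]))
    remap = {c: i for i, c in enumerate(order)}
    labels = {o: remap[c] for o, c in zip(norm.obs_ids, raw)}
    return ClusterLabels(labels=labels, k=k, n_pcs=n_pcs, resolution=resolution,
                         seed=seed)


def batch_center(norm: CountMatrix, batch_key: str = "batch") -> CountMatrix:
    """Per batch and gene, subtract the batch mean and add back the global mean."""
    if batch_key not in norm.obs_meta.columns:
        raise ValidationError(f"obs_meta lacks batch column {batch_key!r}")
    x = norm.dense()
    batches = norm.obs_meta[batch_key].to_numpy()
    global_mean = x.mean(axis=1, keepdims=True)
    out = x.copy()
    for b in pd.unique(batches):
        cols = np.flatnonzero(batches == b)
        if len(cols) == 1:
            logger.warning("batch %r has a single observation; left unchanged", b)
            continue
        out[:, cols] = x[:, cols] - x[:, cols].mean(axis=1, keepdims=True) + global_mean
    return norm.with_values(sp.csr_matrix(out))


def downsample_groups(counts: CountMatrix, group_key: str, seed: int = 0) -> CountMatrix:
    """Subsample every group (without replacement) to the smallest group's size."""
    if group_key not in counts.obs_meta.columns:
        raise ValidationError(f"obs_meta lacks group column {group_key!r}")
    groups = counts.obs_meta[group_key].to_numpy()
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups to downsample")
    sizes = {g: int((groups == g).sum()) for g in uniq}
    if min(sizes.values()) == 0:
        raise ValidationError("empty group")
    n_min = min(sizes.values())
    rng = np.random.default_rng(seed)
    keep: List[int] = []
    for g in sorted(sizes, key=str):
        members = np.flatnonzero(groups == g)
        keep.extend(sorted(rng.choice(members, size=n_min, replace=False)))
    return counts.subset_obs(np.array(sorted(keep), dtype=int))


def score_gene_set(norm: CountMatrix, gene_set: GeneSet, n_bins: int = 25,
                   ctrl_size: int = 50, seed: int = 0) -> GeneScore:
    """Expression-bin-matched control score: mean(target) - mean(control pool).

    Genes are ranked by mean expression and cut into ``n_bins`` equal-size
    bins; each target gene contributes ``ctrl_size`` control genes sampled
    without replacement from its bin.
    """
    present = sorted(g for g in gene_set.members if g in set(norm.gene_ids))
    absent = sorted(gene_set.members - set(present))
    if absent:
        logger.warning("score_gene_set %r: %d member(s) absent, e.g. %s",
                       gene_set.name, len(absent), absent[:3])
    if not present:
        raise ValidationError(f"no member of {gene_set.name!r} present in matrix")
    rng = np.random.default_rng(seed)
    x = norm.values
    gene_mean = np.asarray(x.mean(axis=1)).ravel()
    order = np.lexsort((norm.gene_ids.astype(str), gene_mean))
    bin_of = np.empty(norm.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    gpos = {g: i for i, g in enumerate(norm.gene_ids)}
    target_idx = np.array([gpos[g] for g in present])
    target_set = set(target_idx.tolist())
    ctrl: set = set()
    for gi in target_idx:
        pool = np.flatnonzero(bin_of == bin_of[gi])
        pool = np.array([p for p in pool if p not in target_set], dtype=int)
        if pool.size == 0:
            continue
        chosen = rng.choice(pool, size=min(ctrl_size, pool.size), replace=False)
        ctrl.update(int(c) for c in chosen)
    if not ctrl:
        raise ValidationError("control pool is empty")
    ctrl_idx = np.array(sorted(ctrl), dtype=int)
    tgt = np.asarray(x[target_idx, :].mean(axis=0)).ravel()
    ref = np.asarray(x[ctrl_idx, :].mean(axis=0)).ravel()
    scores = pd.Series(tgt - ref, index=pd.Index(norm.obs_ids, name="obs_id"))
    return GeneScore(scores=scores, set_name=gene_set.name, n_bins=n_bins,
                     ctrl_size=ctrl_size, seed=seed)
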