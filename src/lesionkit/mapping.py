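"""Probabilistic cell-to-spot mapping, deconvolution, and radial cluster profiles.

Cells are softly assigned to spots by maximizing, over a row-stochastic
matrix M (cells x spots), the sum over training genes of the cosine
similarity between the spatial expression vector of the gene and its
prediction M^T S. Optimization is full-batch gradient ascent on the softmax
logits with step rejection (halve the rate when the objective would
decrease), so the objective is non-decreasing over accepted steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .gradient import BinAssignment
from .io_formats import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class MappingMatrix:
    M: np.ndarray  # cells x spots, rows sum to 1
    cell_ids: np.ndarray
    spot_ids: np.ndarray
    training_genes: List[str]
    objective: float
    trace: List[float] = field(default_factory=list)
    gene_cosines: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rs = self.M.sum(axis=1)
        if np.max(np.abs(rs - 1.0)) > 1e-8:
            raise ValidationError("mapping matrix is not row-stochastic")


@dataclass
class DeconvolutionResult:
    assignment: Dict[str, List[str]]  # spot -> assigned cell ids
    composition: pd.DataFrame  # spot x cluster counts
    nuclei_counts: Dict[str, int]


def select_training_genes(sc_markers: Mapping[object, Sequence[str]],
                          spatial_genes: Sequence[str], top_k: int) -> List[str]:
    """Union over clusters of top-k ranked markers, restricted to spatial genes."""
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    spatial = set(spatial_genes)
    chosen: set = set()
    for cluster in sorted(sc_markers, key=str):
        chosen.update(list(sc_markers[cluster])[:top_k])
    out = sorted(chosen & spatial)
    if not out:
        raise ValidationError("no training gene is present in the spatial panel")
    return out


def _unit_columns(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=0)
    norms[norms == 0] = 1.0
    return x / norms


def _softmax_rows(w: np.ndarray) -> np.ndarray:
    w = w - w.max(axis=1, keepdims=True)
    e = np.exp(w)
    return e / e.sum(axis=1, keepdims=True)


def fit_mapping(sc: CountMatrix, spatial: CountMatrix, training_genes: Sequence[str],
                iters: int = 1000, lr: float = 0.1, seed: int = 0,
                init_noise: float = 0.0) -> MappingMatrix:
    """Fit the soft cell-to-spot assignment by per-gene cosine ascent.

    Both matrices must be log-normalized; each training gene is unit-
    normalized across cells and across spots before entering the cosine
    objective. Training genes that are all-zero on either side are dropped
    with a warning.

    Logits start from a scaled cell-by-spot cosine-similarity warm start, so
    cells with identical expression keep identical assignment rows; set
    ``init_noise`` > 0 to add seeded Gaussian jitter on top.
    """
    if spatial.n_obs < 2:
        raise ValidationError("need at least 2 spots")
    sc_set, sp_set = set(sc.gene_ids), set(spatial.gene_ids)
    genes = [g for g in training_genes if g in sc_set and g in sp_set]
    missing = [g for g in training_genes if g not in sc_set or g not in sp_set]
    if missing:
        raise ValidationError(f"training genes absent from inputs: {missing[:5]}")
    S_full = np.asarray(sc.values[sc.gene_index(genes), :].todense(), dtype=float).T
    G_full = np.asarray(spatial.values[spatial.gene_index(genes), :].todense(),
                        dtype=float).T
    keep = []
    for j, g in enumerate(genes):
        if not G_full[:, j].any() or not S_full[:, j].any():
            logger.warning("training gene %r all-zero on one side; dropped", g)
        else:
            keep.append(j)
    if not keep:
        raise ValidationError("all training genes dropped")
    genes = [genes[j] for j in keep]
    S = _unit_columns(S_full[:, keep])  # cells x genes
    G = _unit_columns(G_full[:, keep])  # spots x genes

    n_cells, n_spots = S.shape[0], G.shape[0]
    Su = S / np.maximum(np.linalg.norm(S, axis=1, keepdims=True), 1e-12)
    Gu = G / np.maximum(np.linalg.norm(G, axis=1, keepdims=True), 1e-12)
    W = 0.1 * (Su @ Gu.T)
    if init_noise > 0:
        W = W + np.random.default_rng(seed).normal(0.0, init_noise, size=W.shape)

    def objective_and_grad(w):
        M = _softmax_rows(w)
        P = M.T @ S  # spots x genes
        pg = np.linalg.norm(P, axis=0)
        pg_safe = np.where(pg == 0, 1.0, pg)
        dots = np.einsum("sg,sg->g", G, P)
        cos = dots / pg_safe  # columns of G are unit vectors
        L = float(cos.sum())
        dP = G / pg_safe - P * (dots / pg_safe**3)
        dM = S @ dP.T  # cells x spots
        inner = np.einsum("cs,cs->c", dM, M)
        dW = M * (dM - inner[:, None])
        return L, dW, M, cos

    # Adam ascent with step rejection: a proposed update that would lower the
    # objective is discarded and the rate halved, so the accepted trace is
    # non-decreasing while retaining Adam's per-parameter scaling.
    L, dW, M, cos = objective_and_grad(W)
    trace = [L]
    step = lr
    b1, b2, eps = 0.9, 0.999, 1e-8
    mom = np.zeros_like(W)
    vel = np.zeros_like(W)
    t = 0
    for _ in range(iters):
        t += 1
        mom_new = b1 * mom + (1 - b1) * dW
        vel_new = b2 * vel + (1 - b2) * dW**2
        W_new = W + step * (mom_new / (1 - b1**t)) \
            / (np.sqrt(vel_new / (1 - b2**t)) + eps)
        L_new, dW_new, M_new, cos_new = objective_and_grad(W_new)
        if L_new < L:
            # stale momentum can keep proposing a descent direction; drop it
            step /= 2.0
            mom[:] = 0.0
            vel[:] = 0.0
            if step < 1e-8:
                break
            continue
        W, L, dW, M, cos = W_new, L_new, dW_new, M_new, cos_new
        mom, vel = mom_new, vel_new
        trace.append(L)
    logger.info("fit_mapping: objective %.4f -> %.4f over %d accepted steps",
                trace[0], L, len(trace) - 1)
    return MappingMatrix(M=M, cell_ids=sc.obs_ids, spot_ids=spatial.obs_ids,
                         training_genes=genes, objective=L, trace=trace,
                         gene_cosines=dict(zip(genes, cos.tolist())))


def cluster_spot_probability(mapping: MappingMatrix,
                             cell_clusters: Mapping[str, object]) -> pd.DataFrame:
    """Row-normalized per-cluster spatial probability: P[c,s] = sum_i M[i,s]."""
    unlabeled = [c for c in mapping.cell_ids if c not in cell_clusters]
    if unlabeled:
        raise ValidationError(f"unlabeled cells: {unlabeled[:5]}")
    clusters = sorted({cell_clusters[c] for c in mapping.cell_ids}, key=str)
    rows = []
    for cl in clusters:
        mask = np.array([cell_clusters[c] == cl for c in mapping.cell_ids])
        if not mask.any():
            logger.warning("cluster %r is empty; zero row emitted", cl)
            rows.append(np.zeros(mapping.M.shape[1]))
            continue
        v = mapping.M[mask, :].sum(axis=0)
        total = v.sum()
        rows.append(v / total if total > 0 else v)
    return pd.DataFrame(np.vstack(rows), index=clusters,
                        columns=list(mapping.spot_ids))


def deconvolve(mapping: MappingMatrix, nuclei_counts: Mapping[str, int],
               cell_clusters: Mapping[str, object]) -> DeconvolutionResult:
    """Greedy hard assignment of cells to spots respecting per-spot nuclei counts.

    Repeatedly assigns the globally largest mapping score among unassigned
    cells and unfilled spots; ties break on (cell id, spot id).
    """
    capacity = {s: int(nuclei_counts.get(s, 0)) for s in mapping.spot_ids}
    if any(v < 0 for v in capacity.values()):
        raise ValidationError("negative nuclei count")
    total = sum(capacity.values())
    if total > len(mapping.cell_ids):
        raise ValidationError(
            f"nuclei counts ({total}) exceed available cells ({len(mapping.cell_ids)})")
    cells = list(mapping.cell_ids)
    spots = list(mapping.spot_ids)
    order = sorted(
        ((i, s) for i in range(len(cells)) for s in range(len(spots))
         if capacity[spots[s]] > 0),
        key=lambda t: (-mapping.M[t[0], t[1]], cells[t[0]], spots[t[1]]))
    assigned_cells: set = set()
    remaining = dict(capacity)
    assignment: Dict[str, List[str]] = {s: [] for s in spots}
    n_assigned = 0
    for i, s in order:
        if n_assigned == total:
            break
        if i in assigned_cells or remaining[spots[s]] == 0:
            continue
        assignment[spots[s]].append(cells[i])
        assigned_cells.add(i)
        remaining[spots[s]] -= 1
        n_assigned += 1
    clusters = sorted({cell_clusters[c] for c in cells if c in cell_clusters}, key=str)
    comp = pd.DataFrame(0, index=spots, columns=clusters)
    for s, members in assignment.items():
        for c in members:
            comp.loc[s, cell_clusters[c]] += 1
    return DeconvolutionResult(assignment=assignment, composition=comp,
                               nuclei_counts=capacity)


def radial_cluster_profiles(P: pd.DataFrame, bins: BinAssignment,
                            linkage: str = "average") -> pd.DataFrame:
    """Per-cluster mean mapping probability in each ring, rows in dendrogram leaf order."""
    spot_cols = list(P.columns)
    prof = np.full((len(P), bins.n_bins), np.nan)
    for k in range(1, bins.n_bins + 1):
        members = [s for s in spot_cols if bins.bins.get(s) == k]
        if not members:
            logger.warning("ring %d has no spots; column flagged as missing", k)
            continue
        prof[:, k - 1] = P[members].mean(axis=1).to_numpy()
    out = pd.DataFrame(prof, index=P.index,
                       columns=[f"bin_{k}" for k in range(1, bins.n_bins + 1)])
    if len(out) > 2:
        filled = out.ffill(axis=1).bfill(axis=1).fillna(0.0).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            d = pdist(filled, metric="correlation")
        d = np.nan_to_num(d, nan=1.0)  # constant rows: undefined -> max distance
        z = hierarchy.linkage(d, method=linkage)
        order = hierarchy.leaves_list(z)
        out = out.iloc[order]
    return out
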