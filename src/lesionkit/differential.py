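"""Marker statistics, condition contrasts, set intersections, over-representation.

The marker test is a Welch-type two-sample t statistic with the
"overestimated variance" convention: the rest group's variance term is
divided by the target group's size, which inflates the standard error and
makes the test conservative whenever the rest group is the larger one. The
degrees of freedom use the Welch-Satterthwaite formula under the same
substitution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import NORMALIZED_LOG, CountMatrix, GeneSet
from .preprocess import ClusterLabels

LOG2FC_EPS = 1e-9


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step function of rank)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _log2fc(m_g: np.ndarray, m_r: np.ndarray) -> np.ndarray:
    return np.log2((np.expm1(m_g) + LOG2FC_EPS) / (np.expm1(m_r) + LOG2FC_EPS))


def _group_stats(x: np.ndarray) -> tuple:
    n = x.shape[1]
    m = x.mean(axis=1)
    v = x.var(axis=1, ddof=1) if n > 1 else np.zeros(x.shape[0])
    return n, m, v


def rank_markers(norm: CountMatrix, labels: ClusterLabels | Mapping[str, object],
                 group: object = None) -> pd.DataFrame:
    """Overestimated-variance t test of each cluster against all other observations.

    Returns one row per (group, gene), BH-adjusted within each group, sorted
    by ascending p then gene id within group.
    """
    if norm.layer_flag != NORMALIZED_LOG:
        raise ValidationError("rank_markers expects a log-normalized matrix")
    lab = labels.labels if isinstance(labels, ClusterLabels) else dict(labels)
    y = np.array([lab[o] for o in norm.obs_ids], dtype=object)
    x = norm.dense()
    groups = [group] if group is not None else sorted(set(y), key=str)
    frames = []
    for g in groups:
        in_g = y == g
        if in_g.sum() < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")
        if (~in_g).sum() < 1:
            raise ValidationError(f"group {g!r} has an empty rest group")
        n_g, m_g, v_g = _group_stats(x[:, in_g])
        n_r, m_r, v_r = _group_stats(x[:, ~in_g])
        # overestimated-variance convention: rest variance divided by n_g
        se2 = v_g / n_g + v_r / n_g
        se = np.sqrt(se2)
        diff = m_g - m_r
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                         np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        with np.errstate(invalid="ignore", divide="ignore"):
            df_num = se2**2
            df_den = (v_g / n_g) ** 2 / (n_g - 1) + (v_r / n_g) ** 2 / (n_g - 1)
            dof = np.where(df_den > 0, df_num / np.where(df_den > 0, df_den, 1.0), 1.0)
        p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), dof),
                     np.where(diff == 0, 1.0, 0.0))
        frames.append(pd.DataFrame({
            "gene": norm.gene_ids, "group": g, "mean_in": m_g, "mean_rest": m_r,
            "log2fc": _log2fc(m_g, m_r), "statistic": t, "pval": p,
            "padj": bh_adjust(p)}))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["group", "pval", "gene"], kind="mergesort",
                           ignore_index=True)


def condition_wald_test(norm: CountMatrix, labels: Mapping[str, object] | None,
                        condition_key: str, group1: object, group0: object,
                        subcluster: object = None,
                        cluster_key: str = "cluster") -> pd.DataFrame:
    """Normal-approximation two-group contrast (Wald z) on log-normalized values."""
    if norm.layer_flag != NORMALIZED_LOG:
        raise ValidationError("condition_wald_test expects a log-normalized matrix")
    meta = norm.obs_meta
    mask = np.ones(norm.n_obs, dtype=bool)
    if subcluster is not None:
        if labels is not None:
            lab = labels.labels if isinstance(labels, ClusterLabels) else dict(labels)
            mask &= np.array([lab.get(o) == subcluster for o in norm.obs_ids])
        else:
            mask &= (meta[cluster_key] == subcluster).to_numpy()
    cond = meta[condition_key].to_numpy()
    in1 = mask & (cond == group1)
    in0 = mask & (cond == group0)
    if in1.sum() < 2 or in0.sum() < 2:
        raise ValidationError("both condition groups need >= 2 observations")
    x = norm.dense()
    n1, m1, v1 = _group_stats(x[:, in1])
    n0, m0, v0 = _group_stats(x[:, in0])
    se = np.sqrt(v1 / n1 + v0 / n0)
    diff = m1 - m0
    degenerate = (se == 0) & (diff != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    out = pd.DataFrame({
        "gene": norm.gene_ids, "group": group1, "mean_in": m1, "mean_rest": m0,
        "log2fc": _log2fc(m1, m0), "statistic": z, "pval": p, "skipped": degenerate})
    out.loc[degenerate, ["statistic", "pval"]] = np.nan
    ok = ~out["skipped"]
    out["padj"] = np.nan
    out.loc[ok, "padj"] = bh_adjust(out.loc[ok, "pval"].to_numpy())
    return out.sort_values(["pval", "gene"], kind="mergesort", ignore_index=True)


def filter_degs(table: pd.DataFrame, p_max: float = 0.05, lfc_min_abs: float = 1.6,
                direction: str = "up", use_padj: bool = False) -> List[str]:
    """Genes with pval < p_max and log2fc strictly beyond the threshold."""
    if table.empty:
        raise ValidationError("empty DEG table")
    if direction not in ("up", "down", "both"):
        raise ValidationError(f"unknown direction {direction!r}")
    pcol = "padj" if use_padj else "pval"
    keep = table[pcol] < p_max
    lfc = table["log2fc"]
    if direction == "up":
        keep &= lfc > lfc_min_abs
    elif direction == "down":
        keep &= lfc < -lfc_min_abs
    else:
        keep &= lfc.abs() > lfc_min_abs
    return sorted(table.loc[keep.fillna(False), "gene"].unique())


@dataclass
class IntersectionResult:
    """Exclusive (and inclusive) intersections over a family of named sets."""

    set_names: List[str]
    exclusive: Dict[frozenset, List[str]]  # subset of names -> members only there
    inclusive_sizes: Dict[frozenset, int]
    union_size: int

    def exclusive_size(self, names: Iterable[str]) -> int:
        return len(self.exclusive.get(frozenset(names), []))

    def exclusive_members(self, names: Iterable[str]) -> List[str]:
        return list(self.exclusive.get(frozenset(names), []))


def exclusive_intersections(sets: Mapping[str, Iterable[str]]) -> IntersectionResult:
    """Classify every element of the union by its exact membership signature.

    Exclusive mode assigns each element to the one subset of set names it
    belongs to (so exclusive sizes partition the union); inclusive sizes
    count plain intersections regardless of other memberships.
    """
    if not 1 <= len(sets) <= 20:
        raise ValidationError(f"need 1-20 sets, got {len(sets)}")
    named = {str(k): set(v) for k, v in sets.items()}
    union = sorted(set().union(*named.values())) if named else []
    exclusive: Dict[frozenset, List[str]] = {}
    for el in union:
        sig = frozenset(k for k, v in named.items() if el in v)
        exclusive.setdefault(sig, []).append(el)
    inclusive: Dict[frozenset, int] = {}
    names = sorted(named)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            sig = frozenset(combo)
            if sig in exclusive or r == len(names):
                inter = set.intersection(*(named[c] for c in combo))
                inclusive[sig] = len(inter)
    return IntersectionResult(set_names=names, exclusive=exclusive,
                              inclusive_sizes=inclusive, union_size=len(union))


def over_representation(query: Sequence[str], sets: Sequence[GeneSet],
                        universe: Sequence[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set."""
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    q = set(query)
    dropped = q - uni
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "%d query gene(s) outside the universe dropped", len(dropped))
    q &= uni
    N, n = len(uni), len(q)
    rows = []
    for gs in sets:
        members = gs.members & uni
        K = len(members)
        k = len(members & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"set_name": gs.name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N, "pval": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["pval"].to_numpy())
        out = out.sort_values(["pval", "set_name"], kind="mergesort",
                              ignore_index=True)
    return out


def top_markers(table: pd.DataFrame, k_top: int) -> Dict[object, List[str]]:
    """Per group, the k_top genes with smallest p (ties by gene id)."""
    out: Dict[object, List[str]] = {}
    for g, sub in table.groupby("group", sort=True):
        sub = sub.sort_values(["pval", "gene"], kind="mergesort")
        out[g] = list(sub["gene"].head(k_top))
    return out


def cluster_similarity(markers: Mapping[object, Sequence[str]],
                       k_top: int = 20) -> pd.DataFrame:
    """Jaccard similarity of each pair of clusters' top-k marker lists."""
    names = sorted(markers, key=str)
    tops = {}
    for c in names:
        lst = list(markers[c])
        if len(lst) < k_top:
            import logging

            logging.getLogger(__name__).warning(
                "cluster %r has only %d ranked markers (< k_top=%d)", c, len(lst), k_top)
        tops[c] = set(lst[:k_top])
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in combinations(names, 2):
        inter = len(tops[a] & tops[b])
        un = len(tops[a] | tops[b])
        val = inter / un if un else 1.0
        mat.loc[a, b] = mat.loc[b, a] = val
    return mat
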