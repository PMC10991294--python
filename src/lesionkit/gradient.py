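"""Concentric-ring binning around a lesion and template-model screening.

Spots are binned by Euclidean distance to the boundary of a lesion
annotation: bin 0 is the annotation interior, bin k >= 1 collects spots at
boundary distance d in ((k-1)*w, k*w]. Per-feature radial profiles over the
rings are min-max scaled and correlated against a library of monotone
template curves; features are ranked by the mean, across lesions, of the
one-sided correlation p-value of their best-matching template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .io_formats import NORMALIZED_LOG, CountMatrix, GeneSet, SpotTable

logger = logging.getLogger(__name__)

DEFAULT_BINWIDTH_UM = 95.0
DEFAULT_N_BINS = 13

# Continuous template shapes on x in [0, 1]; the bin-center evaluations used
# for screening are derived from these same callables, and the simulator
# reuses them, so planted structure and screening geometry agree by
# construction.
_DESCENDING: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear_descending": lambda x: 1.0 - x,
    "immediate_descending": lambda x: (1.0 - x) ** 4,
    "late_descending": lambda x: 1.0 - x**4,
    "abrupt_descending": lambda x: 1.0 / (1.0 + np.exp((x - 0.5) / 0.05)),
}


def template_function(name: str) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous template curve by name (descending or ascending)."""
    if name in _DESCENDING:
        return _DESCENDING[name]
    if name.endswith("_ascending"):
        base = name.replace("_ascending", "_descending")
        if base in _DESCENDING:
            return lambda x, _f=_DESCENDING[base]: 1.0 - _f(np.asarray(x, dtype=float))
    raise ValidationError(f"unknown template model {name!r}")


def template_names() -> List[str]:
    names = list(_DESCENDING)
    names += [n.replace("_descending", "_ascending") for n in _DESCENDING]
    return sorted(names)


@dataclass
class TemplateLibrary:
    """Template curves evaluated at ring-bin centers x_k = (k - 1/2)/B."""

    n_bins: int
    curves: Dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.curves[name]

    def names(self) -> List[str]:
        return sorted(self.curves)


def build_templates(n_bins: int) -> TemplateLibrary:
    if n_bins < 4:
        raise ValidationError(f"need at least 4 bins, got {n_bins}")
    x = (np.arange(1, n_bins + 1) - 0.5) / n_bins
    curves = {name: np.clip(template_function(name)(x), 0.0, 1.0)
              for name in template_names()}
    return TemplateLibrary(n_bins=n_bins, curves=curves)


# ---------------------------------------------------------------------------
# Lesion geometry and binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionAnnotation:
    """Circular or polygonal lesion-core annotation in um coordinates."""

    lesion_id: str
    center: tuple | None = None  # (x, y) for circles
    radius: float | None = None
    polygon: tuple | None = None  # ((x1,y1), ...) simple polygon

    def __post_init__(self) -> None:
        if self.polygon is None:
            if self.center is None or self.radius is None:
                raise ValidationError("circle annotation needs center and radius")
            if not self.radius > 0:
                raise ValidationError("annotation radius must be > 0")
        else:
            if len(self.polygon) < 3:
                raise ValidationError("polygon needs at least 3 vertices")
            from shapely.geometry import Polygon

            if not Polygon(self.polygon).is_simple:
                raise ValidationError("polygon is self-intersecting")

    def boundary_distance(self, xy: np.ndarray) -> np.ndarray:
        """0 inside the annotation, else Euclidean distance to its boundary."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.polygon is None:
            d = np.hypot(xy[:, 0] - self.center[0], xy[:, 1] - self.center[1])
            return np.maximum(d - self.radius, 0.0)
        from shapely.geometry import Point, Polygon

        poly = Polygon(self.polygon)
        out = np.empty(len(xy))
        for i, (x, y) in enumerate(xy):
            p = Point(x, y)
            out[i] = 0.0 if poly.covers(p) else p.distance(poly.exterior)
        return out


@dataclass
class BinAssignment:
    """Spot barcode -> concentric bin index (0 = annotation interior)."""

    bins: Dict[str, int]
    binwidth: float
    n_bins: int
    lesion_id: str
    excluded: frozenset = frozenset()

    def barcodes_in_bin(self, k: int) -> List[str]:
        return [b for b, kk in self.bins.items() if kk == k]


def assign_concentric_bins(spots: SpotTable, lesion: LesionAnnotation,
                           binwidth: float = DEFAULT_BINWIDTH_UM,
                           n_bins: int = DEFAULT_N_BINS,
                           exclude_clusters: Iterable | None = None) -> BinAssignment:
    """Bin spots into concentric rings of width ``binwidth`` around the lesion.

    Ring k covers boundary distances ((k-1)*w, k*w]; the upper edge is
    inclusive. Spots beyond n_bins*w, and spots in excluded clusters, are
    left unassigned.
    """
    if binwidth <= 0:
        raise ValidationError("binwidth must be > 0")
    exclude = frozenset(exclude_clusters or ())
    if exclude and spots.df["cluster"].isna().all():
        raise ValidationError("cluster exclusions requested but spots carry no labels")
    d = lesion.boundary_distance(spots.coords())
    edges = np.arange(1, n_bins + 1) * float(binwidth)
    # first k with d <= k*w; identical comparisons to a scalar scan over edges
    k = np.searchsorted(edges, d, side="left") + 1
    inside = d == 0.0
    assigned: Dict[str, int] = {}
    clusters = spots.df["cluster"].tolist()
    for i, barcode in enumerate(spots.barcodes):
        if clusters[i] in exclude:
            continue
        if inside[i]:
            assigned[barcode] = 0
        elif k[i] <= n_bins:
            assigned[barcode] = int(k[i])
    if not assigned:
        raise ValidationError("no spot falls within the binning window")
    if not any(v == 0 for v in assigned.values()):
        logger.warning("lesion %s: no spot inside the annotation (bin 0 empty)",
                       lesion.lesion_id)
    return BinAssignment(bins=assigned, binwidth=float(binwidth), n_bins=int(n_bins),
                         lesion_id=lesion.lesion_id, excluded=exclude)


# ---------------------------------------------------------------------------
# Radial profiles
# ---------------------------------------------------------------------------


@dataclass
class GradientProfile:
    feature_id: str
    lesion_id: str
    ybar: np.ndarray  # bin-wise mean over rings 1..B
    scaled: np.ndarray | None  # min-max scaled ybar; None if constant
    is_constant: bool
    incomplete: bool  # some ring had no spots

    @property
    def n_bins(self) -> int:
        return len(self.ybar)


def compute_profiles(norm: CountMatrix, bins: BinAssignment,
                     features: Sequence) -> List[GradientProfile]:
    """Bin-wise mean expression profiles over rings 1..B for genes or gene sets.

    A gene-set feature's per-spot value is the mean over its member genes
    present in the matrix. The annotation interior (bin 0) is excluded from
    the profile used for screening.
    """
    if norm.layer_flag != NORMALIZED_LOG:
        raise ValidationError("compute_profiles expects a log-normalized matrix")
    obs_pos = {b: j for j, b in enumerate(norm.obs_ids)}
    ring_members: List[np.ndarray] = []
    for k in range(1, bins.n_bins + 1):
        cols = [obs_pos[b] for b in bins.bins if bins.bins[b] == k and b in obs_pos]
        ring_members.append(np.array(sorted(cols), dtype=int))
    incomplete_any = any(len(m) == 0 for m in ring_members)

    gene_feats = [f for f in features if not isinstance(f, GeneSet)]
    set_feats = [f for f in features if isinstance(f, GeneSet)]
    rows: List[tuple] = []
    if gene_feats:
        idx = norm.gene_index(gene_feats)
        sub = norm.values[idx, :]
        for name, i in zip(gene_feats, range(len(idx))):
            rows.append((str(name), sub[i, :]))
    gene_lookup = {g: i for i, g in enumerate(norm.gene_ids)}
    for gs in set_feats:
        present = sorted(g for g in gs.members if g in gene_lookup)
        if not present:
            logger.warning("gene set %r has no members in the matrix; skipped", gs.name)
            continue
        if len(present) < len(gs.members):
            logger.warning("gene set %r: %d/%d members absent from matrix", gs.name,
                           len(gs.members) - len(present), len(gs.members))
        sub = norm.values[[gene_lookup[g] for g in present], :]
        rows.append((gs.name, sub.mean(axis=0)))

    profiles = []
    for name, vec in rows:
        vec = np.asarray(vec.todense() if hasattr(vec, "todense") else vec).ravel()
        ybar = np.array([vec[m].mean() if len(m) else np.nan for m in ring_members])
        finite = ybar[np.isfinite(ybar)]
        constant = finite.size == 0 or np.isclose(finite.max(), finite.min())
        scaled = None
        if not constant:
            scaled = (ybar - np.nanmin(ybar)) / (np.nanmax(ybar) - np.nanmin(ybar))
        else:
            logger.warning("feature %r has a constant radial profile; flagged", name)
        profiles.append(GradientProfile(feature_id=name, lesion_id=bins.lesion_id,
                                        ybar=ybar, scaled=scaled, is_constant=constant,
                                        incomplete=incomplete_any))
    return profiles


def profiles_matrix(norm: CountMatrix, bins: BinAssignment) -> tuple:
    """Vectorized all-gene ring means: (gene_ids, genes x B matrix)."""
    obs_pos = {b: j for j, b in enumerate(norm.obs_ids)}
    B = bins.n_bins
    n_obs = norm.n_obs
    member = np.zeros((n_obs, B))
    for b, k in bins.bins.items():
        if 1 <= k <= B and b in obs_pos:
            member[obs_pos[b], k - 1] = 1.0
    counts = member.sum(axis=0)
    sums = norm.values @ member
    with np.errstate(invalid="ignore"):
        means = np.asarray(sums) / counts
    return norm.gene_ids, means


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


@dataclass
class ScreeningResult:
    feature_id: str
    lesion_id: str
    best_model: str
    r: float
    p: float
    model_r: Dict[str, float]
    model_p: Dict[str, float]
    ybar: np.ndarray
    p_value_mean: float = field(default=np.nan)


def _one_sided_p(r: float, n_bins: int) -> float:
    if r >= 1.0:
        return np.finfo(float).tiny
    if r <= -1.0:
        return 1.0
    t = r * np.sqrt((n_bins - 2) / (1.0 - r * r))
    return float(stats.t.sf(t, df=n_bins - 2))


def screen_profiles(profiles: Sequence[GradientProfile], templates: TemplateLibrary,
                    min_total_counts: int = 50,
                    raw_totals: Mapping[str, float] | None = None) -> List[ScreeningResult]:
    """Correlate each profile with every template; pick the best by Pearson r.

    Genes whose raw total count is not strictly greater than
    ``min_total_counts`` are omitted (gene sets are exempt: they carry no
    entry in ``raw_totals``). p-values are one-sided for positive r with
    B - 2 degrees of freedom.
    """
    results = []
    for prof in profiles:
        if prof.is_constant:
            continue
        if prof.n_bins != templates.n_bins:
            raise ValidationError(
                f"profile {prof.feature_id!r} has {prof.n_bins} bins, "
                f"templates have {templates.n_bins}"
            )
        if raw_totals is not None and prof.feature_id in raw_totals:
            if not raw_totals[prof.feature_id] > min_total_counts:
                continue
        y = prof.scaled
        ok = np.isfinite(y)
        if ok.sum() < 3:
            continue
        model_r, model_p = {}, {}
        for name in templates.names():
            f = templates[name][ok]
            if np.std(f) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(y[ok], f)[0, 1])
            model_r[name] = r
            model_p[name] = _one_sided_p(r, int(ok.sum()))
        best = min(model_r, key=lambda m: (-model_r[m], m))
        results.append(ScreeningResult(
            feature_id=prof.feature_id, lesion_id=prof.lesion_id, best_model=best,
            r=model_r[best], p=model_p[best], model_r=model_r, model_p=model_p,
            ybar=prof.ybar, p_value_mean=model_p[best]))
    return results


def merge_lesions(per_lesion: Mapping[str, Sequence[ScreeningResult]]) -> List[ScreeningResult]:
    """Merge per-lesion screens: bin-wise mean profile, per-model mean r and p.

    The reported best model maximizes the mean r across lesions;
    p_value_mean is the arithmetic mean of that model's per-lesion p-values.
    Output is sorted ascending by p_value_mean (ties by feature id).
    """
    if not per_lesion:
        raise ValidationError("no lesions to merge")
    lesions = sorted(per_lesion)
    by_feature: Dict[str, Dict[str, ScreeningResult]] = {}
    n_bins_seen = set()
    for lesion in lesions:
        for res in per_lesion[lesion]:
            n_bins_seen.add(len(res.ybar))
            by_feature.setdefault(res.feature_id, {})[lesion] = res
    if len(n_bins_seen) > 1:
        raise ValidationError(f"lesions screened with different bin counts: {n_bins_seen}")
    merged = []
    for fid in sorted(by_feature):
        entries = by_feature[fid]
        if len(entries) < len(lesions):
            continue  # feature must survive screening in every lesion
        models = sorted(next(iter(entries.values())).model_r)
        mean_r = {m: float(np.mean([entries[l].model_r[m] for l in lesions])) for m in models}
        mean_p = {m: float(np.mean([entries[l].model_p[m] for l in lesions])) for m in models}
        best = min(mean_r, key=lambda m: (-mean_r[m], m))
        ybar = np.mean([entries[l].ybar for l in lesions], axis=0)
        merged.append(ScreeningResult(
            feature_id=fid, lesion_id="merged", best_model=best, r=mean_r[best],
            p=mean_p[best], model_r=mean_r, model_p=mean_p, ybar=ybar,
            p_value_mean=mean_p[best]))
    merged.sort(key=lambda s: (s.p_value_mean, s.feature_id))
    return merged


def results_to_records(results: Sequence[ScreeningResult]) -> List[dict]:
    recs = []
    for s in results:
        recs.append({"feature_id": s.feature_id, "lesion_id": s.lesion_id,
                     "best_model": s.best_model, "r": s.r, "p": s.p,
                     "p_value_mean": s.p_value_mean})
    return recs
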