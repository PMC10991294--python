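"""Synthetic spatial and single-cell count data with ground truth.

Counts follow a negative-binomial law parameterized by (mean, dispersion
theta), so variance = mu + mu^2/theta. A spot's counts are the sum of its
1-10 constituent cells' draws; for cells of one type this sum is again
negative binomial with mean m*mu and dispersion m*theta, which is how the
aggregated sampling path draws it. Radial structure reuses the screening
module's template curves, so planted shapes and screened shapes agree by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .gradient import DEFAULT_BINWIDTH_UM, DEFAULT_N_BINS, template_function
from .io_formats import RAW, CountMatrix, SpotTable


@dataclass
class GroundTruth:
    """Planted structure accompanying a simulated dataset (fields optional)."""

    gene_truth: Optional[pd.DataFrame] = None  # gene, template, amplitude
    spot_truth: Optional[pd.DataFrame] = None  # barcode, distance, xnorm, bin, n_cells
    composition: Optional[pd.DataFrame] = None  # spot x cell-type fractions
    cell_truth: Optional[pd.DataFrame] = None  # cell_id, spot, cell_type, state, ...
    cell_counts: Optional[CountMatrix] = None
    programs: Optional[Dict[str, List[str]]] = None
    batch_factors: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# Spatial simulation
# ---------------------------------------------------------------------------


@dataclass
class SpatialSimConfig:
    n_rows: int = 39
    n_cols: int = 39
    pitch_um: float = 100.0
    lattice: str = "square"  # or "hex"
    lesion_center: Optional[Tuple[float, float]] = None  # defaults to grid center
    core_radius: float = 200.0
    n_genes: int = 2000
    n_gradient_genes: Dict[str, int] = field(default_factory=lambda: {
        "linear_descending": 100, "immediate_descending": 100,
        "abrupt_descending": 100, "late_descending": 100})
    amplitude: float = 2.0
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 0.5
    n_housekeeping: int = 100  # high-expression genes dominating library size
    housekeeping_mean: float = 200.0
    dispersion: float = 10.0
    cells_per_spot: Tuple[int, int] = (1, 10)
    libsize_sigma: float = 0.15
    n_cell_types: int = 0
    n_type_markers: int = 50
    type_marker_lfc: float = 2.0
    binwidth_um: float = DEFAULT_BINWIDTH_UM
    n_bins: int = DEFAULT_N_BINS
    emit_cells: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        lo, hi = self.cells_per_spot
        if not (1 <= lo <= hi):
            raise ValidationError("cells_per_spot must satisfy 1 <= lo <= hi")
        if sum(self.n_gradient_genes.values()) > self.n_genes:
            raise ValidationError("more gradient genes than genes")
        if self.lattice not in ("square", "hex"):
            raise ValidationError(f"unknown lattice {self.lattice!r}")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")


def _lattice_coords(cfg: SpatialSimConfig) -> np.ndarray:
    rows = np.arange(cfg.n_rows)
    cols = np.arange(cfg.n_cols)
    if cfg.lattice == "square":
        xs = np.repeat(cols[None, :], cfg.n_rows, axis=0) * cfg.pitch_um
        ys = np.repeat(rows[:, None], cfg.n_cols, axis=1) * cfg.pitch_um
    else:  # hex: odd rows offset by half a pitch, rows sqrt(3)/2 apart
        xs = (np.repeat(cols[None, :], cfg.n_rows, axis=0)
              + 0.5 * (rows[:, None] % 2)) * cfg.pitch_um
        ys = np.repeat(rows[:, None], cfg.n_cols, axis=1) * cfg.pitch_um * np.sqrt(3) / 2
    return np.column_stack([xs.ravel(), ys.ravel()])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, shape: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw of NB(mean, dispersion=shape); zeros where mean==0."""
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    lam = rng.gamma(shape=np.broadcast_to(shape, mean.shape)[pos],
                    scale=mean[pos] / np.broadcast_to(shape, mean.shape)[pos])
    out[pos] = rng.poisson(lam)
    return out


def simulate_spatial(cfg: SpatialSimConfig) -> Tuple[CountMatrix, SpotTable, GroundTruth]:
    """Simulate a spot lattice with a circular lesion core and radial gene structure.

    Gradient gene g with template f and amplitude a has per-cell NB mean
    mu_g * (1 + a * f(x_s)) at spot s, where x_s is the spot's boundary
    distance normalized by the screening window n_bins * binwidth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    coords = _lattice_coords(cfg)
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    center = cfg.lesion_center or ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)
    if not (xmin <= center[0] <= xmax and ymin <= center[1] <= ymax):
        raise ValidationError(f"lesion center {center} outside grid "
                              f"[{xmin},{xmax}]x[{ymin},{ymax}]")
    n_spots = len(coords)
    barcodes = np.array([f"SP{i:05d}" for i in range(n_spots)], dtype=object)
    dist = np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1])
    d = np.maximum(dist - cfg.core_radius, 0.0)
    window = cfg.n_bins * cfg.binwidth_um
    xnorm = np.clip(d / window, 0.0, 1.0)

    gene_ids = np.array([f"G{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    base_mu = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    n_grad_total = sum(cfg.n_gradient_genes.values())
    if cfg.n_housekeeping:
        if n_grad_total + cfg.n_housekeeping > cfg.n_genes:
            raise ValidationError("housekeeping block overlaps gradient genes")
        base_mu[cfg.n_genes - cfg.n_housekeeping:] = cfg.housekeeping_mean

    templates = np.array([""] * cfg.n_genes, dtype=object)
    amplitudes = np.zeros(cfg.n_genes)
    gi = 0
    grad_factor = np.ones((cfg.n_genes, n_spots))
    for model in sorted(cfg.n_gradient_genes):
        n = cfg.n_gradient_genes[model]
        f = template_function(model)(xnorm)
        for _ in range(n):
            templates[gi] = model
            amplitudes[gi] = cfg.amplitude
            grad_factor[gi, :] = 1.0 + cfg.amplitude * f
            gi += 1

    # Cell types: each type up-regulates an exclusive marker block.
    K = max(cfg.n_cell_types, 1)
    type_names = [f"T{t}" for t in range(K)]
    type_factor = np.ones((cfg.n_genes, K))
    if cfg.n_cell_types > 1:
        start = gi
        for t in range(K):
            block = slice(start + t * cfg.n_type_markers,
                          start + (t + 1) * cfg.n_type_markers)
            if block.stop > cfg.n_genes:
                raise ValidationError("not enough genes for type marker blocks")
            type_factor[block, t] = 2.0 ** cfg.type_marker_lfc

    lo, hi = cfg.cells_per_spot
    n_cells = rng.integers(lo, hi + 1, size=n_spots)
    if cfg.n_cell_types > 1:
        probs = rng.dirichlet(np.ones(K), size=n_spots)
        comp = np.vstack([rng.multinomial(n_cells[s], probs[s]) for s in range(n_spots)])
    else:
        comp = n_cells[:, None]
    lib = rng.lognormal(0.0, cfg.libsize_sigma, size=n_spots) if cfg.libsize_sigma > 0 \
        else np.ones(n_spots)

    cell_truth = None
    cell_counts = None
    if cfg.emit_cells:
        # Per-cell draws; spot counts are their literal sums.
        records = []
        cell_mats = []
        for s in range(n_spots):
            for t in range(K):
                for _ in range(comp[s, t]):
                    records.append((f"C{len(records):06d}", barcodes[s], type_names[t]))
        counts_spots = np.zeros((cfg.n_genes, n_spots), dtype=np.int64)
        for cid, bc, tname in records:
            s = int(bc[2:])
            t = type_names.index(tname)
            mean = base_mu * type_factor[:, t] * grad_factor[:, s] * lib[s]
            draw = _nb_draw(rng, mean, np.full(cfg.n_genes, cfg.dispersion))
            cell_mats.append(draw)
            counts_spots[:, s] += draw
        cell_ids = np.array([r[0] for r in records], dtype=object)
        cell_truth = pd.DataFrame(records, columns=["cell_id", "spot", "cell_type"])
        cell_counts = CountMatrix(
            values=sp.csr_matrix(np.column_stack(cell_mats)),
            gene_ids=gene_ids, obs_ids=cell_ids,
            obs_meta=cell_truth.set_index("cell_id")[["cell_type"]], layer_flag=RAW)
        counts = counts_spots
    else:
        # Aggregated path: per type, m same-mean cells sum to NB(m*mu, m*theta).
        counts = np.zeros((cfg.n_genes, n_spots), dtype=np.int64)
        for t in range(K):
            m = comp[:, t].astype(float)
            mean = (base_mu[:, None] * type_factor[:, t][:, None]) * grad_factor \
                * (m * lib)[None, :]
            shape = np.broadcast_to((m * cfg.dispersion)[None, :], mean.shape).copy()
            shape[shape == 0] = 1.0  # unused where mean == 0
            counts += _nb_draw(rng, mean, shape)

    values = sp.csr_matrix(counts)
    obs_meta = pd.DataFrame({"sample": "sim", "condition": "INJ",
                             "batch": "B0"}, index=pd.Index(barcodes, name="obs_id"))
    cm = CountMatrix(values=values, gene_ids=gene_ids, obs_ids=barcodes,
                     obs_meta=obs_meta, layer_flag=RAW)
    spots = SpotTable(pd.DataFrame({
        "barcode": barcodes, "x_um": coords[:, 0], "y_um": coords[:, 1],
        "in_tissue": True, "cluster": "cortex"}))

    edges = np.arange(1, cfg.n_bins + 1) * cfg.binwidth_um
    bins = np.where(d == 0.0, 0, np.searchsorted(edges, d, side="left") + 1)
    bins = np.where((bins > cfg.n_bins) & (d > 0), -1, bins)
    truth = GroundTruth(
        gene_truth=pd.DataFrame({"gene": gene_ids, "template": templates,
                                 "amplitude": amplitudes, "base_mean": base_mu}),
        spot_truth=pd.DataFrame({"barcode": barcodes, "distance": d, "xnorm": xnorm,
                                 "bin": bins, "n_cells": n_cells}),
        composition=pd.DataFrame(comp / n_cells[:, None], columns=type_names,
                                 index=pd.Index(barcodes, name="barcode")),
        cell_truth=cell_truth, cell_counts=cell_counts)
    return cm, spots, truth


# ---------------------------------------------------------------------------
# Single-cell simulation
# ---------------------------------------------------------------------------


@dataclass
class ScSimConfig:
    cell_types: Tuple[str, ...] = ("Astro", "Micro", "OPC")
    n_homeostatic: int = 150  # per type
    n_reactive: int = 100  # per type, injured condition only
    n_genes: int = 2000
    n_shared: int = 50
    shared_lfc: float = 2.0
    n_reactivity: int = 30  # per type
    reactivity_lfc: float = 2.0
    n_proliferation: int = 30
    proliferation_lfc: float = 2.0
    proliferation_fraction: float = 0.3
    n_type_markers: int = 50
    type_marker_lfc: float = 2.0
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 0.4
    program_base_mean: float = 2.0
    dispersion: float = 10.0
    libsize_sigma: float = 0.2
    n_batches: int = 1
    batch_sigma: float = 0.0
    shared_genes: Optional[Sequence[str]] = None  # explicit program overrides
    proliferation_genes: Optional[Sequence[str]] = None
    reactivity_genes: Optional[Dict[str, Sequence[str]]] = None
    allow_program_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        for v in (self.n_shared, self.n_reactivity, self.n_proliferation,
                  self.n_type_markers):
            if v < 0:
                raise ValidationError("program sizes must be >= 0")
        if not 0 <= self.proliferation_fraction <= 1:
            raise ValidationError("proliferation_fraction must be in [0, 1]")
        explicit = [list(self.shared_genes or [])]
        explicit.append(list(self.proliferation_genes or []))
        for t in (self.reactivity_genes or {}):
            explicit.append(list(self.reactivity_genes[t]))
        flat = [g for lst in explicit for g in lst]
        if flat and not self.allow_program_overlap and len(flat) != len(set(flat)):
            raise ValidationError("program gene lists overlap")


def simulate_scrna(cfg: ScSimConfig) -> Tuple[CountMatrix, GroundTruth]:
    """Simulate cell-type clusters with injury-reactive subpopulations.

    Reactive cells of each type up-regulate their type's reactivity program
    and the shared inflammatory program by the configured log2 fold change; a
    configured fraction of reactive cells additionally expresses the
    proliferation program. Batch effects are per-batch multiplicative gene
    factors.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_ids = np.array([f"G{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    gpos = {g: i for i, g in enumerate(gene_ids)}

    # Carve disjoint program blocks unless explicit lists are given.
    cursor = 0

    def take(n: int) -> List[str]:
        nonlocal cursor
        block = list(gene_ids[cursor:cursor + n])
        cursor += n
        if cursor > cfg.n_genes:
            raise ValidationError("not enough genes for requested programs")
        return block

    programs: Dict[str, List[str]] = {}
    programs["shared_inflammatory"] = list(cfg.shared_genes) if cfg.shared_genes \
        else take(cfg.n_shared)
    programs["proliferation"] = list(cfg.proliferation_genes) if cfg.proliferation_genes \
        else take(cfg.n_proliferation)
    for t in cfg.cell_types:
        key = f"reactivity_{t}"
        if cfg.reactivity_genes and t in cfg.reactivity_genes:
            programs[key] = list(cfg.reactivity_genes[t])
        else:
            programs[key] = take(cfg.n_reactivity)
    for t in cfg.cell_types:
        programs[f"markers_{t}"] = take(cfg.n_type_markers)
    for name, members in programs.items():
        missing = [g for g in members if g not in gpos]
        if missing:
            raise ValidationError(f"program {name!r} references unknown genes {missing[:3]}")

    base_mu = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    if cfg.program_base_mean is not None:
        for name, members in programs.items():
            base_mu[[gpos[g] for g in members]] = cfg.program_base_mean

    # Cell roster: homeostatic cells split between conditions, reactive in INJ.
    rows = []
    for t in cfg.cell_types:
        for i in range(cfg.n_homeostatic):
            cond = "INT" if i % 2 == 0 else "INJ"
            rows.append((t, "homeostatic", cond))
        for _ in range(cfg.n_reactive):
            rows.append((t, "reactive", "INJ"))
    n_cells = len(rows)
    order = rng.permutation(n_cells)
    rows = [rows[i] for i in order]
    batches = [f"B{i % cfg.n_batches}" for i in range(n_cells)]
    proliferating = np.zeros(n_cells, dtype=bool)
    reactive_mask = np.array([r[1] == "reactive" for r in rows])
    proliferating[reactive_mask] = rng.random(int(reactive_mask.sum())) \
        < cfg.proliferation_fraction

    batch_factors = np.ones((cfg.n_batches, cfg.n_genes))
    if cfg.batch_sigma > 0:
        batch_factors = rng.lognormal(0.0, cfg.batch_sigma,
                                      size=(cfg.n_batches, cfg.n_genes))
    lib = rng.lognormal(0.0, cfg.libsize_sigma, size=n_cells) if cfg.libsize_sigma > 0 \
        else np.ones(n_cells)

    lfc_factor = np.ones((n_cells, cfg.n_genes))
    for t in cfg.cell_types:
        mask = np.array([r[0] == t for r in rows])
        idx = [gpos[g] for g in programs[f"markers_{t}"]]
        lfc_factor[np.ix_(mask, idx)] *= 2.0 ** cfg.type_marker_lfc
        rmask = mask & reactive_mask
        ridx = [gpos[g] for g in programs[f"reactivity_{t}"]]
        lfc_factor[np.ix_(rmask, ridx)] *= 2.0 ** cfg.reactivity_lfc
        sidx = [gpos[g] for g in programs["shared_inflammatory"]]
        lfc_factor[np.ix_(rmask, sidx)] *= 2.0 ** cfg.shared_lfc
    pidx = [gpos[g] for g in programs["proliferation"]]
    lfc_factor[np.ix_(proliferating, pidx)] *= 2.0 ** cfg.proliferation_lfc

    bidx = np.array([int(b[1:]) for b in batches])
    mean = base_mu[None, :] * lfc_factor * batch_factors[bidx, :] * lib[:, None]
    counts = _nb_draw(rng, mean, np.full(mean.shape, cfg.dispersion))

    cell_ids = np.array([f"C{i:06d}" for i in range(n_cells)], dtype=object)
    obs_meta = pd.DataFrame({
        "sample": [f"{r[2]}_{b}" for r, b in zip(rows, batches)],
        "condition": [r[2] for r in rows],
        "batch": batches,
    }, index=pd.Index(cell_ids, name="obs_id"))
    cm = CountMatrix(values=sp.csr_matrix(counts.T), gene_ids=gene_ids,
                     obs_ids=cell_ids, obs_meta=obs_meta, layer_flag=RAW)
    cell_truth = pd.DataFrame({
        "cell_id": cell_ids,
        "cell_type": [r[0] for r in rows],
        "state": [r[1] for r in rows],
        "condition": [r[2] for r in rows],
        "batch": batches,
        "proliferating": proliferating,
    })
    truth = GroundTruth(
        cell_truth=cell_truth, programs=programs,
        batch_factors=pd.DataFrame(batch_factors,
                                   index=[f"B{i}" for i in range(cfg.n_batches)],
                                   columns=gene_ids))
    return cm, truth
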