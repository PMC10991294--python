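"""Interchange formats: sparse count matrices, spot positions, gene sets, TSV tables.

All geometry downstream of :func:`read_spot_positions` is expressed in
micrometers; pixel coordinates are converted once, at read time, via a
caller-supplied scale factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

RAW = "raw"
NORMALIZED_LOG = "normalized_log"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x observation expression matrix with per-observation metadata.

    ``values`` is stored genes-in-rows, observations-in-columns (CSR). The
    ``layer_flag`` distinguishes raw integer counts from log-normalized
    values; raw matrices must be nonnegative integers.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    obs_ids: np.ndarray
    obs_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    layer_flag: str = RAW

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.obs_ids = np.asarray(self.obs_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.obs_ids)) != len(self.obs_ids):
            raise ValidationError("duplicate observation ids")
        if self.layer_flag not in (RAW, NORMALIZED_LOG):
            raise ValidationError(f"unknown layer flag {self.layer_flag!r}")
        if self.layer_flag == RAW:
            data = self.values.data
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise ValidationError("raw layer must contain nonnegative integers")
        if self.obs_meta is None or len(self.obs_meta) == 0:
            self.obs_meta = pd.DataFrame(index=pd.Index(self.obs_ids, name="obs_id"))
        else:
            self.obs_meta = self.obs_meta.copy()
            self.obs_meta.index = pd.Index(self.obs_ids, name="obs_id")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def counts_per_obs(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def genes_detected_per_obs(self) -> np.ndarray:
        return np.asarray((self.values > 0).sum(axis=0)).ravel()

    def counts_per_gene(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_obs(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            values=self.values[:, idx].tocsr(),
            gene_ids=self.gene_ids,
            obs_ids=self.obs_ids[idx],
            obs_meta=self.obs_meta.iloc[idx],
            layer_flag=self.layer_flag,
        )

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = self.gene_index(genes)
        return CountMatrix(
            values=self.values[idx, :].tocsr(),
            gene_ids=self.gene_ids[idx],
            obs_ids=self.obs_ids,
            obs_meta=self.obs_meta,
            layer_flag=self.layer_flag,
        )

    def dense(self) -> np.ndarray:
        """Dense genes x obs float array."""
        return np.asarray(self.values.todense(), dtype=float)

    def with_values(self, values, layer_flag: str | None = None) -> "CountMatrix":
        return CountMatrix(
            values=sp.csr_matrix(values),
            gene_ids=self.gene_ids,
            obs_ids=self.obs_ids,
            obs_meta=self.obs_meta,
            layer_flag=layer_flag or self.layer_flag,
        )


@dataclass
class SpotTable:
    """Per-spot geometry for a spatial capture array (coordinates in um)."""

    df: pd.DataFrame  # columns: barcode, x_um, y_um, in_tissue, cluster

    REQUIRED = ("barcode", "x_um", "y_um", "in_tissue")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValidationError(f"SpotTable missing column {col!r}")
        if "cluster" not in self.df.columns:
            self.df = self.df.assign(cluster=pd.NA)
        if self.df["barcode"].duplicated().any():
            raise ValidationError("duplicate spot barcodes")
        coords = self.df[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite spot coordinates")
        self.df = self.df.reset_index(drop=True)

    @property
    def barcodes(self) -> np.ndarray:
        return self.df["barcode"].to_numpy(dtype=object)

    def coords(self) -> np.ndarray:
        return self.df[["x_um", "y_um"]].to_numpy(dtype=float)

    def with_clusters(self, labels: Mapping[str, object]) -> "SpotTable":
        df = self.df.copy()
        df["cluster"] = [labels.get(b, pd.NA) for b in df["barcode"]]
        return SpotTable(df)


@dataclass(frozen=True)
class GeneSet:
    """Named collection of gene symbols."""

    name: str
    description: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")


# ---------------------------------------------------------------------------
# Count matrix IO (MatrixMarket triplet + feature/barcode tables)
# ---------------------------------------------------------------------------


def read_counts(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet with line-aligned feature/barcode lists."""
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    genes = _read_feature_column(features_path)
    barcodes = [ln for ln in Path(barcodes_path).read_text().splitlines() if ln.strip()]
    barcodes = [ln.split("\t")[0] for ln in barcodes]
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape} but features/barcodes declare "
            f"{len(genes)} x {len(barcodes)}"
        )
    if mat.data.size and (np.any(mat.data < 0) or np.any(mat.data != np.round(mat.data))):
        raise ValidationError("count matrix entries must be nonnegative integers")
    values = sp.csr_matrix((mat.data.astype(np.int64), (mat.row, mat.col)), shape=mat.shape)
    return CountMatrix(values=values, gene_ids=np.array(genes, dtype=object),
                       obs_ids=np.array(barcodes, dtype=object), layer_flag=RAW)


def _read_feature_column(features_path) -> list:
    lines = [ln for ln in Path(features_path).read_text().splitlines() if ln.strip()]
    out = []
    for ln in lines:
        fields = ln.split("\t")
        # 10x features.tsv carries (id, symbol, type); we key on the symbol.
        out.append(fields[1] if len(fields) >= 2 else fields[0])
    return out


def write_counts(cm: CountMatrix, out_dir) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv (+ obs_meta.tsv) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cm.layer_flag == RAW:
        mat = cm.values.tocoo().astype(np.int64)
        scipy.io.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    else:
        scipy.io.mmwrite(str(out / "matrix.mtx"), cm.values.tocoo(), field="real", precision=12)
    (out / "features.tsv").write_text("".join(f"{g}\n" for g in cm.gene_ids))
    (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in cm.obs_ids))
    if len(cm.obs_meta.columns):
        meta = cm.obs_meta.reset_index()
        write_table(meta, out / "obs_meta.tsv")


def read_counts_dir(in_dir) -> CountMatrix:
    """Inverse of :func:`write_counts`. Restores obs_meta and layer flag."""
    d = Path(in_dir)
    header = (d / "matrix.mtx").read_text().splitlines()[0]
    cm = _read_counts_any(d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv",
                          raw="integer" in header)
    meta_path = d / "obs_meta.tsv"
    if meta_path.exists():
        meta = read_table(meta_path).set_index("obs_id")
        cm = CountMatrix(cm.values, cm.gene_ids, cm.obs_ids,
                         obs_meta=meta.loc[list(cm.obs_ids)], layer_flag=cm.layer_flag)
    return cm


def _read_counts_any(matrix_path, features_path, barcodes_path, raw: bool) -> CountMatrix:
    if raw:
        return read_counts(matrix_path, features_path, barcodes_path)
    mat = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    genes = _read_feature_column(features_path)
    barcodes = [ln.split("\t")[0] for ln in Path(barcodes_path).read_text().splitlines()
                if ln.strip()]
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError("matrix dimensions do not match features/barcodes")
    return CountMatrix(values=mat, gene_ids=np.array(genes, dtype=object),
                       obs_ids=np.array(barcodes, dtype=object), layer_flag=NORMALIZED_LOG)


# ---------------------------------------------------------------------------
# Spot positions (Visium tissue-positions dialect)
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                     "pxl_row_in_fullres", "pxl_col_in_fullres"]


def read_spot_positions(path, um_per_px: float = 1.0,
                        keep_only_in_tissue: bool = True) -> SpotTable:
    """Read a tissue-positions CSV, converting pixel coordinates to micrometers."""
    if not (um_per_px > 0) or not math.isfinite(um_per_px):
        raise ValidationError(f"um_per_px must be positive and finite, got {um_per_px}")
    first = Path(path).read_text().splitlines()
    if not first:
        raise FormatError(f"empty positions file {path}")
    has_header = "barcode" in first[0]
    df = pd.read_csv(path, header=0 if has_header else None)
    if not has_header:
        if df.shape[1] != len(_POSITION_COLUMNS):
            raise FormatError(
                f"positions file has {df.shape[1]} columns, expected {len(_POSITION_COLUMNS)}"
            )
        df.columns = _POSITION_COLUMNS
    missing = [c for c in _POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"positions file missing columns {missing}")
    out = pd.DataFrame({
        "barcode": df["barcode"].astype(str),
        "x_um": df["pxl_col_in_fullres"].astype(float) * um_per_px,
        "y_um": df["pxl_row_in_fullres"].astype(float) * um_per_px,
        "in_tissue": df["in_tissue"].astype(int).astype(bool),
    })
    if keep_only_in_tissue:
        out = out[out["in_tissue"]].reset_index(drop=True)
    return SpotTable(out)


def write_spot_positions(spots: SpotTable, path, um_per_px: float = 1.0) -> None:
    """Write a header-bearing tissue-positions CSV (inverse of read at same scale)."""
    df = spots.df
    out = pd.DataFrame({
        "barcode": df["barcode"],
        "in_tissue": df["in_tissue"].astype(int),
        "array_row": 0,
        "array_col": 0,
        "pxl_row_in_fullres": df["y_um"] / um_per_px,
        "pxl_col_in_fullres": df["x_um"] / um_per_px,
    })
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path) -> list:
    """Read a GMT file: name, description, then member genes, tab-separated."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
        name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
        if len(set(members)) != len(members):
            logger.warning("gene set %r has duplicate members; deduplicating", name)
        sets.append(GeneSet(name=name, description=desc, members=frozenset(members)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description] + sorted(gs.members)) + "\n")


# ---------------------------------------------------------------------------
# Generic TSV tables
# ---------------------------------------------------------------------------


def write_table(records, path, sort_by: Sequence[str] | None = None) -> None:
    """Write records as a UTF-8 TSV with a header and deterministic row order.

    Non-finite floats are rendered as "NA". ``records`` may be a DataFrame or
    a sequence of mappings.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if records and not all(isinstance(r, Mapping) for r in records):
            raise ValidationError("records must be mappings or a DataFrame")
        df = pd.DataFrame(records)
    for col in df.columns:
        if df[col].map(lambda v: isinstance(v, (list, dict, set))).any():
            raise ValidationError(f"column {col!r} holds unserializable containers")
    if sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort").reset_index(drop=True)
    float_cols = df.select_dtypes(include=[np.floating]).columns
    if len(float_cols):
        df[float_cols] = df[float_cols].replace([np.inf, -np.inf], np.nan)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g",
              encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)


def replace_layer(cm: CountMatrix, layer_flag: str) -> CountMatrix:
    return replace(cm, layer_flag=layer_flag)
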