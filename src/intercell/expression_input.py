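"""Expression-matrix, cluster-label and DEG-table ingestion.

The pipeline consumes *already normalized* single-cell expression (e.g. the
log-normalized output of an upstream Seurat/scanpy run) together with a
cell -> cluster assignment and a per-cluster differential-expression table.
This module aligns the three inputs and reduces the matrix to per-cluster
mean-expression profiles, which is the expression summary used by the
scoring formulas downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

DEG_COLUMNS = ("gene", "cluster", "log2fc", "adj_p")

#: Default DEG thresholds: fold-change cut used throughout comparison
#: protocols, and the conventional 5% adjusted-significance level.
DEFAULT_MIN_ABS_LOG2FC = 0.25
DEFAULT_MAX_ADJ_P = 0.05


@dataclass
class LabeledExpression:
    """Genes x cells normalized expression with cluster labels.

    ``matrix`` is dense float64 (genes in rows); ``labels`` maps every
    retained barcode to exactly one cluster name.
    """

    matrix: np.ndarray
    gene_index: pd.Index
    cell_index: pd.Index
    labels: pd.Series  # indexed by barcode -> cluster name

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_index = pd.Index(self.gene_index)
        self.cell_index = pd.Index(self.cell_index)
        if self.matrix.shape != (len(self.gene_index), len(self.cell_index)):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_index)} genes x {len(self.cell_index)} cells"
            )
        if self.gene_index.has_duplicates:
            dups = self.gene_index[self.gene_index.duplicated()].unique()
            raise ValidationError(
                f"duplicate gene symbols after normalization: {list(dups)[:5]}"
            )
        if self.cell_index.has_duplicates:
            raise ValidationError("duplicate cell barcodes")
        self.labels = pd.Series(self.labels)
        missing = self.cell_index.difference(self.labels.index)
        if len(missing):
            raise ValidationError(
                f"{len(missing)} cells have no cluster label"
            )
        self.labels = self.labels.loc[self.cell_index]
        if (self.matrix < 0).any():
            raise ValidationError(
                "expression matrix contains negative values; expected "
                "non-negative normalized expression (raw counts or "
                "log-normalized), not a z-scored matrix"
            )

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    @property
    def clusters(self) -> list[str]:
        return sorted(self.labels.unique())

    def gene_row(self, gene: str) -> np.ndarray:
        if gene not in self.gene_index:
            raise ValidationError(f"gene {gene!r} not in expression matrix")
        return self.matrix[self.gene_index.get_loc(gene)]

    def label_codes(self) -> tuple[np.ndarray, list[str]]:
        """Integer-coded labels aligned with the cell axis."""
        cats = self.clusters
        codes = pd.Categorical(
            self.labels.values, categories=cats
        ).codes.astype(np.intp)
        return codes, cats


@dataclass(frozen=True)
class DegEntry:
    gene: str
    cluster: str
    log2fc: float
    adj_p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.adj_p <= 1.0):
            raise ValidationError(
                f"adjusted p {self.adj_p} outside [0, 1] "
                f"({self.gene} / {self.cluster})"
            )


@dataclass
class ClusterProfile:
    """Per-cluster mean of normalized expression."""

    cluster: str
    mean_expr: pd.Series  # gene -> mean
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("a cluster must contain at least one cell")


def _read_dense_matrix(matrix_path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)


def _read_mtx(matrix_path, features_path, barcodes_path):
    m = mmread(str(matrix_path))
    mat = np.asarray(m.toarray() if hasattr(m, "toarray") else m, dtype=float)
    genes = pd.read_csv(features_path, sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
    if mat.shape != (len(genes), len(cells)):
        raise SchemaError(
            f"matrix {mat.shape} inconsistent with {len(genes)} features "
            f"and {len(cells)} barcodes"
        )
    return mat, genes, cells


def read_labels(labels_path) -> pd.Series:
    df = pd.read_csv(
        labels_path, sep="\t", header=None, names=["barcode", "cluster"],
        dtype=str,
    )
    if df["barcode"].iloc[0] == "barcode":  # tolerate a header row
        df = df.iloc[1:]
    return pd.Series(
        df["cluster"].values, index=df["barcode"].values, name="cluster"
    )


def read_expression(
    matrix_path,
    labels_path,
    features_path=None,
    barcodes_path=None,
    deduplicate: bool = False,
) -> LabeledExpression:
    """Load a dense TSV or MatrixMarket expression matrix with labels.

    Cells missing a label are dropped (count logged).  A barcode set
    disjoint from the label file is fatal.  Duplicate feature symbols are
    fatal unless ``deduplicate`` keeps the highest-total row per symbol.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx" or str(matrix_path).endswith(".mtx.gz"):
        if features_path is None or barcodes_path is None:
            raise SchemaError(
                "MatrixMarket input requires features_path and barcodes_path"
            )
        mat, genes, cells = _read_mtx(matrix_path, features_path, barcodes_path)
    else:
        mat, genes, cells = _read_dense_matrix(matrix_path)

    gene_index = pd.Index(genes)
    if gene_index.has_duplicates:
        if not deduplicate:
            dups = gene_index[gene_index.duplicated()].unique()
            raise ValidationError(
                f"duplicate feature symbols {list(dups)[:5]}; pass "
                f"deduplicate=True to keep the highest-total row per symbol"
            )
        totals = mat.sum(axis=1)
        order = np.lexsort((-totals, gene_index.to_numpy()))
        keep_mask = ~pd.Index(gene_index.to_numpy()[order]).duplicated()
        keep = np.sort(order[keep_mask])
        mat, gene_index = mat[keep], gene_index[keep]

    labels = read_labels(labels_path)
    cell_index = pd.Index(cells)
    labeled = cell_index.intersection(labels.index)
    if len(labeled) == 0:
        raise ValidationError(
            "no overlap between matrix barcodes and label file"
        )
    n_dropped = len(cell_index) - len(labeled)
    if n_dropped:
        logger.info("dropped %d cells without a cluster label", n_dropped)
        keep_cells = cell_index.get_indexer(labeled)
        mat = mat[:, keep_cells]
        cell_index = labeled
    return LabeledExpression(
        matrix=mat,
        gene_index=gene_index,
        cell_index=cell_index,
        labels=labels.loc[cell_index],
    )


def cluster_profiles(x: LabeledExpression) -> list[ClusterProfile]:
    """Arithmetic mean of normalized expression per cluster."""
    codes, cats = x.label_codes()
    profiles = []
    for ci, cluster in enumerate(cats):
        mask = codes == ci
        means = x.matrix[:, mask].mean(axis=1)
        profiles.append(
            ClusterProfile(
                cluster=cluster,
                mean_expr=pd.Series(means, index=x.gene_index),
                n_cells=int(mask.sum()),
            )
        )
    return profiles


def read_deg_table(path) -> list[DegEntry]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"DEG table {path}: missing column(s) {missing}")
    return [
        DegEntry(
            gene=str(r.gene),
            cluster=str(r.cluster),
            log2fc=float(r.log2fc),
            adj_p=float(r.adj_p),
        )
        for r in df.itertuples(index=False)
    ]


def write_deg_table(degs: Sequence[DegEntry], path) -> None:
    pd.DataFrame(
        [(d.gene, d.cluster, d.log2fc, d.adj_p) for d in degs],
        columns=DEG_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def select_regulated(
    degs: Iterable[DegEntry],
    cluster: str,
    direction: str = "up",
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    max_adj_p: float = DEFAULT_MAX_ADJ_P,
) -> set[str]:
    """DEG-based gene selection for one cluster.

    Keeps genes with |log2FC| strictly above ``min_abs_log2fc``, a
    sign consistent with ``direction`` (up / down / both), and adjusted p
    at or below ``max_adj_p``.
    """
    if direction not in ("up", "down", "both"):
        raise ValidationError(
            f"direction must be up/down/both, got {direction!r}"
        )
    if min_abs_log2fc < 0:
        raise ValidationError("min_abs_log2fc must be >= 0")
    if not (0.0 <= max_adj_p <= 1.0):
        raise ValidationError("max_adj_p must lie in [0, 1]")
    degs = list(degs)
    known_clusters = {d.cluster for d in degs}
    if cluster not in known_clusters:
        raise ValidationError(
            f"cluster {cluster!r} absent from the DEG table "
            f"(known: {sorted(known_clusters)})"
        )
    out = set()
    for d in degs:
        if d.cluster != cluster:
            continue
        if abs(d.log2fc) <= min_abs_log2fc or d.adj_p > max_adj_p:
            continue
        if direction == "up" and d.log2fc <= 0:
            continue
        if direction == "down" and d.log2fc >= 0:
            continue
        out.add(d.gene)
    return out
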