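"""Shared data containers used across the pipeline.

These are thin, validated dataclasses: a count matrix with sidecar metadata,
a curated variant record, an exon model, gene sets, and the 2x2 enrichment
outcome that every overlap analysis in the package reports.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Controlled vocabulary for variant effect classes.
EFFECTS = ("nonsense", "frameshift", "splicing", "missense", "synonymous",
           "noncoding", "other")
#: Effect classes counted as loss of function.
LOF_EFFECTS = frozenset({"nonsense", "frameshift", "splicing"})
#: Effect classes located in exons or splice sites (denominator of the
#: de novo exonic/splicing percentages).
EXONIC_EFFECTS = frozenset({"nonsense", "frameshift", "splicing", "missense",
                            "synonymous"})
#: Controlled vocabulary for inheritance.
INHERITANCE = ("de_novo", "inherited", "unknown")

#: Fixed column order of the sorted-cell reference (neurons first: it is the
#: fold-change reference).
SORTED_CELL_TYPES = ("neurons", "astrocytes", "oligodendrocytes",
                     "microglia", "OPC")

#: Developmental stages of the exon-level expression data.
STAGES = ("PN", "EC", "AD")


@dataclass(frozen=True)
class VariantRecord:
    """One curated variant: the atom of the mutation landscape."""

    variant_id: str
    gene: str
    effect: str
    inheritance: str
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(
                f"variant {self.variant_id!r}: unknown effect {self.effect!r}; "
                f"expected one of {EFFECTS}")
        if self.inheritance not in INHERITANCE:
            raise ValueError(
                f"variant {self.variant_id!r}: unknown inheritance "
                f"{self.inheritance!r}; expected one of {INHERITANCE}")
        if self.effect in EXONIC_EFFECTS and not self.gene:
            raise ValueError(
                f"variant {self.variant_id!r}: exonic/splicing effect "
                f"{self.effect!r} requires a gene symbol")


@dataclass
class GeneSet:
    """A named set of gene symbols with free-text provenance."""

    name: str
    genes: set
    provenance: str = ""

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        if any(not g for g in self.genes):
            raise ValueError(f"gene set {self.name!r} contains empty symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class ExonRecord:
    """Exon length, non-synonymous mutation count and per-stage expression."""

    gene: str
    exon_index: int
    length_bp: int
    nonsyn_count: int
    expr: Mapping[str, float]  # stage -> RPKM-like value

    def __post_init__(self) -> None:
        if self.exon_index < 1:
            raise ValueError("exon_index must be >= 1")
        if self.length_bp < 1:
            raise ValueError(
                f"{self.gene} exon {self.exon_index}: length_bp must be >= 1")
        if self.nonsyn_count < 0:
            raise ValueError("nonsyn_count must be >= 0")
        missing = set(STAGES) - set(self.expr)
        if missing:
            raise ValueError(
                f"{self.gene} exon {self.exon_index}: missing stages {missing}")


@dataclass
class EnrichmentResult:
    """Outcome of one 2x2 overlap test (shared by all enrichment analyses).

    ``odds_ratio`` is the sample cross-product ratio of the 2x2 table induced
    by the universe; ``p`` the test p-value; ``p_adj`` filled by batch
    correction (defaults to ``p`` for a single test).
    """

    set_a_name: str
    set_b_name: str
    universe_size: int
    a_size: int
    b_size: int
    overlap: int
    odds_ratio: float
    p: float
    p_adj: float
    method: str  # "fisher" or "proportion"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.overlap > min(self.a_size, self.b_size):
            raise ValueError("overlap exceeds the smaller set")
        if not self.degenerate and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


class ExpressionMatrix:
    """Cells x genes expression with per-cell metadata and gene symbols.

    ``matrix`` may be dense or scipy sparse; rows are cells (in the order of
    ``cell_meta.index``), columns are genes (``gene_ids``).
    """

    def __init__(self, matrix, cell_meta: pd.DataFrame,
                 gene_ids: Sequence[str]):
        gene_ids = np.asarray(gene_ids, dtype=object)
        if matrix.shape != (len(cell_meta), len(gene_ids)):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match "
                f"{len(cell_meta)} cells x {len(gene_ids)} genes")
        if cell_meta.index.has_duplicates:
            raise ValueError("duplicate cell ids in cell_meta")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene symbols")
        self.matrix = matrix
        self.cell_meta = cell_meta
        self.gene_ids = gene_ids

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def cell_ids(self) -> np.ndarray:
        return np.asarray(self.cell_meta.index, dtype=object)

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return np.asarray(self.matrix.todense())
        return np.asarray(self.matrix)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)


class CellByGeneCounts(ExpressionMatrix):
    """Integer count matrix; input to normalisation, clustering and DE."""

    def __init__(self, matrix, cell_meta: pd.DataFrame,
                 gene_ids: Sequence[str]):
        data = matrix.data if sp.issparse(matrix) else np.asarray(matrix)
        if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
            raise ValueError("counts must be non-negative integers")
        super().__init__(matrix, cell_meta, gene_ids)


@dataclass
class ClusterLabeling:
    """Cluster assignment for every cell, with the parameters that made it."""

    labels: np.ndarray  # 0-based integer cluster per cell
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")

    @property
    def n_cells(self) -> int:
        return self.labels.size

    @property
    def sizes(self) -> dict:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    @property
    def cluster_ids(self) -> list:
        return sorted(set(self.labels.tolist()))


@dataclass
class SpatioTemporalExpr:
    """Gene x (region, period) non-negative expression grid.

    ``values`` is a DataFrame indexed by gene with a (region, period)
    MultiIndex on the columns; the grid is complete.
    """

    values: pd.DataFrame
    regions: tuple
    periods: tuple

    def __post_init__(self) -> None:
        expected = pd.MultiIndex.from_product(
            [self.regions, self.periods], names=["region", "period"])
        if not self.values.columns.equals(expected):
            self.values = self.values.reindex(columns=expected)
        if self.values.isna().any().any():
            raise ValueError("incomplete region x period grid")

    @property
    def genes(self) -> np.ndarray:
        return np.asarray(self.values.index, dtype=object)


@dataclass
class SortedCellExpr:
    """Gene x sorted-cell-type mean expression, neurons as FC reference."""

    values: pd.DataFrame  # genes x cell types
    species: str = "human"
    detection: Optional[pd.Series] = None  # gene -> fraction of cells detected

    def __post_init__(self) -> None:
        if "neurons" not in self.values.columns:
            raise ValueError("neurons column is required (fold-change reference)")

    @property
    def genes(self) -> np.ndarray:
        return np.asarray(self.values.index, dtype=object)

    @property
    def cell_types(self) -> list:
        return list(self.values.columns)
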