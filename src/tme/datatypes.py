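"""Core in-memory containers shared across the pipeline.

The single-cell matrix is kept genes x cells (10x triplet orientation);
all code addresses it as (gene, cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class RepertoireTable:
    """Per-sample TCR-beta repertoire: unique amino-acid CDR templates with counts.

    ``counts`` may hold raw template counts or cpm-scaled values; ``is_cpm``
    records which. Templates are unique within a sample.
    """

    sample_id: str
    mouse_id: str
    timepoint: str
    templates: np.ndarray  # unicode array of CDR amino-acid sequences
    counts: np.ndarray  # float array, >= 0
    is_cpm: bool = False

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=object)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.templates.shape != self.counts.shape:
            raise ValueError("templates and counts must align")
        if len(np.unique(self.templates)) != len(self.templates):
            raise ValueError("templates must be unique within a sample")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.any(self.counts > 0):
            raise ValueError("repertoire must contain at least one count > 0")

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=pd.Index(self.templates, name="template"))


@dataclass
class SparseCounts:
    """Sparse UMI count matrix, genes x cells, with per-cell/per-gene metadata."""

    matrix: sp.csr_matrix  # genes x cells, integral counts
    genes: pd.Index
    cells: pd.Index
    cell_conditions: pd.Series  # indexed like cells
    mito: np.ndarray  # bool per gene
    cell_samples: pd.Series | None = None

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.matrix.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise FormatError("UMI counts must be non-negative")
        self.mito = np.asarray(self.mito, dtype=bool)
        if self.mito.shape[0] != len(self.genes):
            raise ValueError("mito flag length must match genes")
        self.cell_conditions = pd.Series(self.cell_conditions)
        self.cell_conditions.index = self.cells

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "SparseCounts":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        if gm.dtype != bool:
            tmp = np.zeros(self.n_genes, bool)
            tmp[gm] = True
            gm = tmp
        if cm.dtype != bool:
            tmp = np.zeros(self.n_cells, bool)
            tmp[cm] = True
            cm = tmp
        return SparseCounts(
            matrix=self.matrix[gm][:, cm],
            genes=self.genes[gm],
            cells=self.cells[cm],
            cell_conditions=self.cell_conditions[cm],
            mito=self.mito[gm],
            cell_samples=None if self.cell_samples is None else self.cell_samples[cm],
        )


@dataclass
class BulkCounts:
    """Bulk RNA-seq genes x samples integer counts with gene lengths (bases)."""

    counts: pd.DataFrame  # genes x samples
    gene_lengths: pd.Series | None = None  # bases, > 0
    sample_conditions: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("bulk counts must be non-negative")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            if (self.gene_lengths <= 0).any():
                raise ValueError("gene lengths must be positive")


@dataclass
class NormalizedMatrix:
    """Log-normalized expression N[i,j] = ln(1 + count * scale / cell_total)."""

    matrix: sp.csr_matrix  # genes x cells, float
    genes: pd.Index
    cells: pd.Index
    scale_factor: float
    cell_conditions: pd.Series | None = None
    cell_samples: pd.Series | None = None

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CellCovariates:
    """Per-cell technical/cell-cycle covariates used by the scaling regression."""

    n_umi: np.ndarray
    mito_ratio: np.ndarray
    s_score: np.ndarray | None = None
    g2m_score: np.ndarray | None = None

    @property
    def cc_difference(self) -> np.ndarray | None:
        if self.s_score is None or self.g2m_score is None:
            return None
        return self.s_score - self.g2m_score


@dataclass
class ClusterAssignment:
    """Cell -> cluster labels (1..k by decreasing size) with provenance."""

    labels: np.ndarray  # int, per cell
    cells: pd.Index
    resolution: float
    seed: int | None = None
    method: str = "leiden"

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()


@dataclass
class Signature:
    """Named cell type with an ordered marker gene list and derivation metadata."""

    cell_type: str
    genes: list[str]
    fdr: float | None = None
    top_k: int | None = None
    n_lists: int | None = None


@dataclass
class MstTrajectory:
    """MST over sub-cluster centroids with per-node size and condition mix."""

    node_ids: list[int]
    sizes: dict[int, int]
    composition: dict[int, dict[str, float]]  # node -> condition -> fraction
    centroids: dict[int, np.ndarray]
    edges: list[tuple[int, int, float]]

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "id": int(n),
                    "size": int(self.sizes[n]),
                    "composition": {k: float(v) for k, v in self.composition[n].items()},
                    "centroid": [float(x) for x in self.centroids[n]],
                }
                for n in self.node_ids
            ],
            "edges": [
                {"source": int(u), "target": int(v), "weight": float(w)}
                for u, v, w in self.edges
            ],
        }
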