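"""Convenience wrapper running the full single-cell pipeline end to end."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterParams, cluster_cells
from .datatypes import ClusterAssignment, NormalizedMatrix, SparseCounts
from .qc import (
    HvgParams,
    QcParams,
    compute_covariates,
    log_normalize,
    pca_embed,
    regress_and_scale,
    select_hvg,
)


@dataclass
class ScPipelineResult:
    counts: SparseCounts  # post-QC raw counts
    norm: NormalizedMatrix
    scaled: np.ndarray
    hvg_mask: np.ndarray
    embedding: np.ndarray
    assignment: ClusterAssignment
    qc_report: dict


def run_sc_pipeline(
    counts: SparseCounts,
    qc_params: QcParams | None = None,
    hvg_params: HvgParams | None = None,
    n_pcs: int = 25,
    cluster_params: ClusterParams | None = None,
    s_genes: list[str] | None = None,
    g2m_genes: list[str] | None = None,
) -> ScPipelineResult:
    """QC -> normalize -> covariate scaling -> HVG -> PCA -> cluster."""
    from .qc import qc_filter

    filtered, report = qc_filter(counts, qc_params)
    norm = log_normalize(filtered)
    cov = compute_covariates(filtered, norm, s_genes=s_genes, g2m_genes=g2m_genes)
    scaled = regress_and_scale(norm, cov)
    hvg = select_hvg(norm, hvg_params)
    n_pcs_eff = min(n_pcs, int(hvg.sum()), filtered.n_cells - 1)
    if n_pcs_eff < 2:
        raise ValueError("too few highly variable genes or cells for an embedding")
    emb = pca_embed(scaled, hvg, n_pcs=n_pcs_eff)
    assignment = cluster_cells(emb, cluster_params or ClusterParams())
    return ScPipelineResult(filtered, norm, scaled, hvg, emb, assignment, report)
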