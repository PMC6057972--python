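"""Single-cell QC, normalization, covariate-regression scaling, HVG selection, PCA.

The processing order mirrors the standard droplet workflow: cells are dropped
on detected-gene count and mitochondrial fraction, counts are log-normalized
per cell, lowly expressed genes are dropped on their normalized mean,
expression is scaled by regressing out technical covariates and z-scoring
residuals, highly variable genes are picked by binned dispersion z-score,
and cells are embedded on the top principal components of the HVG-restricted
scaled matrix. All thresholds use strict inequalities: a cell with exactly
300 detected genes or a mitochondrial ratio of exactly 0.1 is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .datatypes import CellCovariates, NormalizedMatrix, SparseCounts


class ParameterError(ValueError):
    pass


@dataclass
class QcParams:
    min_genes_per_cell: int = 300  # drop cells detecting fewer unique genes
    max_mito_ratio: float = 0.1  # drop cells with mito/endogenous ratio above this
    min_gene_mean: float = 0.01  # drop genes with mean normalized expression below

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ParameterError("min_genes_per_cell must be >= 0")
        if not 0 < self.max_mito_ratio <= 1:
            raise ParameterError("max_mito_ratio must be in (0, 1]")


@dataclass
class HvgParams:
    mean_low: float = 0.01  # keep genes with mean expression strictly above
    mean_high: float = 3.0  # ... and at most this
    dispersion_z_cutoff: float = 0.5
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.mean_low >= self.mean_high:
            raise ParameterError("mean_low must be < mean_high")

    @classmethod
    def for_panel(cls, n_genes: int, scale_factor: float = 10_000.0, **kw) -> "HvgParams":
        """Mean-expression band rescaled to a gene panel of a given size.

        The default (0.01, 3] band targets a whole-transcriptome matrix where
        per-gene normalized means average ~0.5 (scale factor 1e4 over ~2e4
        genes). Because per-cell normalized totals are fixed at the scale
        factor, average per-gene expression grows as the panel shrinks; the
        band is therefore expressed in units of the panel's average
        (scale_factor / n_genes) to keep its meaning across panel sizes.
        """
        avg = scale_factor / n_genes
        return cls(mean_low=0.01 * avg / 0.5, mean_high=3.0 * avg / 0.5, **kw)


def mito_ratio(counts: SparseCounts) -> np.ndarray:
    """Per-cell ratio of mitochondrial to endogenous (non-mito) counts."""
    mito_sum = np.asarray(counts.matrix[counts.mito].sum(axis=0)).ravel()
    endo_sum = np.asarray(counts.matrix[~counts.mito].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(endo_sum > 0, mito_sum / np.maximum(endo_sum, 1), np.inf)
    return ratio


def qc_filter(
    counts: SparseCounts, params: QcParams | None = None, scale_factor: float = 10_000.0
) -> tuple[SparseCounts, dict]:
    """Drop low-complexity and high-mito cells, then lowly expressed genes.

    The gene filter uses the mean log-normalized expression of the retained
    cells, so it runs after cell filtering and normalization. Returns the
    filtered raw counts and a report of how many records each step removed.
    """
    params = params or QcParams()
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("empty matrix")

    genes_per_cell = np.asarray((counts.matrix > 0).sum(axis=0)).ravel()
    keep_genes_cells = genes_per_cell >= params.min_genes_per_cell
    ratio = mito_ratio(counts)
    keep_mito = ratio <= params.max_mito_ratio  # "exceeding 0.1" is strict
    keep_cells = keep_genes_cells & keep_mito
    report = {
        "cells_in": counts.n_cells,
        "cells_dropped_genes": int((~keep_genes_cells).sum()),
        "cells_dropped_mito": int((keep_genes_cells & ~keep_mito).sum()),
        "genes_in": counts.n_genes,
    }
    if not keep_cells.any():
        raise ValueError("QC removed every cell")

    filtered = counts.subset(cell_mask=keep_cells)
    norm = log_normalize(filtered, scale_factor)
    gene_means = np.asarray(norm.matrix.mean(axis=1)).ravel()
    keep_genes = gene_means >= params.min_gene_mean
    report["genes_dropped"] = int((~keep_genes).sum())
    report["cells_out"] = int(keep_cells.sum())
    report["genes_out"] = int(keep_genes.sum())
    return filtered.subset(gene_mask=keep_genes), report


def log_normalize(counts: SparseCounts, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """N[i,j] = ln(1 + count[i,j] * scale_factor / total[j]); zeros stay sparse."""
    totals = np.asarray(counts.matrix.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts must be removed before normalization")
    mat = counts.matrix.tocsc(copy=True).astype(float)
    for j in range(mat.shape[1]):
        sl = slice(mat.indptr[j], mat.indptr[j + 1])
        mat.data[sl] = np.log1p(mat.data[sl] * scale_factor / totals[j])
    return NormalizedMatrix(
        matrix=mat.tocsr(),
        genes=counts.genes,
        cells=counts.cells,
        scale_factor=scale_factor,
        cell_conditions=counts.cell_conditions,
        cell_samples=counts.cell_samples,
    )


def compute_covariates(
    counts: SparseCounts,
    norm: NormalizedMatrix,
    s_genes: list[str] | None = None,
    g2m_genes: list[str] | None = None,
    n_ctrl_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> CellCovariates:
    """UMI totals, mito ratio and (optionally) cell-cycle scores per cell."""
    n_umi = np.asarray(counts.matrix.sum(axis=0)).ravel()
    ratio = mito_ratio(counts)
    s = g2m = None
    if s_genes is not None:
        s = cell_cycle_score(norm, s_genes, n_ctrl_bins, ctrl_size, seed)
    if g2m_genes is not None:
        g2m = cell_cycle_score(norm, g2m_genes, n_ctrl_bins, ctrl_size, seed + 1)
    return CellCovariates(n_umi=n_umi, mito_ratio=ratio, s_score=s, g2m_score=g2m)


def cell_cycle_score(
    norm: NormalizedMatrix,
    gene_set: list[str],
    n_ctrl_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Mean expression of a gene set minus an expression-matched control mean.

    Genes are binned into ``n_ctrl_bins`` equal-frequency bins of mean
    expression; for each set gene, ``ctrl_size`` control genes are drawn
    (with replacement if needed) from its bin. Deterministic given seed.
    """
    idx = norm.genes.get_indexer([g for g in gene_set if g in norm.genes])
    idx = idx[idx >= 0]
    if idx.size == 0:
        raise ValueError("gene set has no overlap with the matrix")
    rng = np.random.default_rng(seed)
    dense_means = np.asarray(norm.matrix.mean(axis=1)).ravel()
    order = np.argsort(dense_means, kind="stable")
    n_bins = min(n_ctrl_bins, norm.n_genes)
    bins = np.empty(norm.n_genes, int)
    bins[order] = np.arange(norm.n_genes) * n_bins // norm.n_genes

    ctrl_idx = []
    for gi in idx:
        pool = np.flatnonzero(bins == bins[gi])
        take = rng.choice(pool, size=min(ctrl_size, pool.size), replace=False)
        ctrl_idx.append(take)
    ctrl_idx = np.unique(np.concatenate(ctrl_idx))

    set_mean = np.asarray(norm.matrix[idx].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(norm.matrix[ctrl_idx].mean(axis=0)).ravel()
    return set_mean - ctrl_mean


def regress_and_scale(
    norm: NormalizedMatrix,
    covariates: CellCovariates | None = None,
    clip: float = 10.0,
) -> np.ndarray:
    """Regress out covariates per gene, z-score residuals, clip at +/- clip.

    Per gene, ordinary least squares of N on (n_umi, mito_ratio,
    cc_difference) with intercept; residuals are standardized to mean 0,
    sd 1. A constant gene scales to the all-zero row. With constant
    covariates this reduces exactly to a per-gene z-score.
    Returns a dense genes x cells array.
    """
    Y = np.asarray(norm.matrix.todense(), float).T  # cells x genes
    n_cells = Y.shape[0]
    cols = [np.ones(n_cells)]
    if covariates is not None:
        cols.append(np.asarray(covariates.n_umi, float))
        cols.append(np.asarray(covariates.mito_ratio, float))
        ccd = covariates.cc_difference
        if ccd is not None:
            cols.append(np.asarray(ccd, float))
    X = np.column_stack(cols)
    # drop constant covariate columns (keep intercept) to keep lstsq well-posed
    keep = [0] + [k for k in range(1, X.shape[1]) if np.ptp(X[:, k]) > 0]
    X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=0)
    # genes fitted (numerically) perfectly or constant scale to all-zero
    # rather than amplifying rounding noise
    sd_tol = 1e-10 * max(1.0, float(np.abs(Y).max()))
    ok = sd > sd_tol
    z = np.where(ok, (resid - resid.mean(axis=0)) / np.where(ok, sd, 1.0), 0.0)
    return np.clip(z.T, -clip, clip)  # genes x cells


def select_hvg(norm: NormalizedMatrix, params: HvgParams | None = None) -> np.ndarray:
    """Highly variable genes by binned dispersion z-score.

    Dispersion is var/mean of the de-logged expression C = e^N - 1 per gene.
    Genes are split into ``n_bins`` equal-frequency bins of mean C; within
    each bin dispersions are z-scored (a singleton bin gets z = 0). Keeps
    genes with mean in (mean_low, mean_high] and z > dispersion_z_cutoff.
    Returns a boolean gene mask.
    """
    params = params or HvgParams()
    if norm.n_genes < params.n_bins:
        raise ParameterError("need at least n_bins genes")
    C = norm.matrix.copy()
    C.data = np.expm1(C.data)
    mean = np.asarray(C.mean(axis=1)).ravel()
    sq = C.copy()
    sq.data = sq.data**2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    var *= norm.n_cells / max(norm.n_cells - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)

    order = np.argsort(mean, kind="stable")
    bins = np.empty(norm.n_genes, int)
    bins[order] = np.arange(norm.n_genes) * params.n_bins // norm.n_genes
    z = np.zeros(norm.n_genes)
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        if members.size < 2:
            continue
        mu, sd = disp[members].mean(), disp[members].std(ddof=0)
        if sd > 0:
            z[members] = (disp[members] - mu) / sd
    return (mean > params.mean_low) & (mean <= params.mean_high) & (
        z > params.dispersion_z_cutoff
    )


def pca_embed(scaled: np.ndarray, hvg_mask: np.ndarray, n_pcs: int = 25) -> np.ndarray:
    """Cell scores on the top principal axes of the HVG-restricted scaled matrix.

    Sign convention: each component's largest-magnitude loading is positive,
    so the embedding is fully deterministic. Returns cells x n_pcs.
    """
    hvg_mask = np.asarray(hvg_mask)
    if hvg_mask.dtype == bool:
        X = scaled[hvg_mask].T  # cells x hvg
    else:
        X = scaled[np.asarray(hvg_mask, int)].T
    if n_pcs > min(X.shape):
        raise ParameterError(f"n_pcs={n_pcs} exceeds matrix rank bound {min(X.shape)}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(X)
    for k in range(n_pcs):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            emb[:, k] *= -1
    return emb
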