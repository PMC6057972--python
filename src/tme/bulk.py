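"""Bulk RNA-seq preprocessing: CPM/RPKM, expression filter, concordance, DEG filter.

The expression filter keeps genes with CPM strictly above a threshold in at
least a minimum number of samples. Sample concordance is the squared Pearson
correlation of log2(RPKM + 1) over expressed genes. The DEG filter partitions
an externally supplied differential-expression table (from any fit, e.g. a
negative-binomial GLM) on strict FDR and |logFC| cutoffs; differential model
fitting itself is out of scope here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import BulkCounts


def cpm(bulk: BulkCounts) -> pd.DataFrame:
    """Counts per million: count * 1e6 / sample total."""
    totals = bulk.counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("samples with zero total counts")
    return bulk.counts * 1e6 / totals


def filter_expressed(bulk: BulkCounts, cpm_min: float = 1.0, min_samples: int = 2) -> pd.Index:
    """Genes with CPM strictly greater than ``cpm_min`` in >= ``min_samples`` samples."""
    if bulk.counts.shape[1] < min_samples:
        raise ValueError("fewer samples than min_samples")
    c = cpm(bulk)
    keep = (c > cpm_min).sum(axis=1) >= min_samples
    return bulk.counts.index[keep]


def rpkm(bulk: BulkCounts) -> pd.DataFrame:
    """Reads per kilobase per million: count * 1e9 / (sample total * gene length)."""
    if bulk.gene_lengths is None:
        raise ValueError("gene lengths required for RPKM")
    totals = bulk.counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("samples with zero total counts")
    return bulk.counts.mul(1e9, axis=0).div(totals, axis=1).div(bulk.gene_lengths, axis=0)


def rpkm_r2(bulk: BulkCounts, expressed: pd.Index, pseudocount: float = 1.0) -> pd.DataFrame:
    """Pairwise R^2 of log2(RPKM + pseudocount) over expressed genes.

    Symmetric with unit diagonal; depth-invariant, so a sample and its
    uniformly depth-scaled copy have R^2 = 1.
    """
    if len(expressed) < 2:
        raise ValueError("need >= 2 expressed genes for correlation")
    lr = np.log2(rpkm(bulk).loc[expressed] + pseudocount)
    r = np.corrcoef(lr.values.T)
    r2 = pd.DataFrame(r**2, index=lr.columns, columns=lr.columns)
    np.fill_diagonal(r2.values, 1.0)
    return r2


def deg_filter(
    de: pd.DataFrame, fdr_max: float = 0.01, abs_logfc_min: float = 1.5
) -> tuple[pd.Index, pd.Index]:
    """Split a DE table into (up, down) gene lists on strict cutoffs.

    ``de`` needs columns gene (or a gene index), logFC (log2) and FDR.
    up: FDR < fdr_max and logFC > abs_logfc_min; down: FDR < fdr_max and
    logFC < -abs_logfc_min. Both inequalities are strict, so a gene at
    exactly the cutoff is excluded.
    """
    if "gene" in de.columns:
        de = de.set_index("gene")
    if not de["FDR"].between(0, 1).all():
        raise ValueError("FDR must lie in [0, 1]")
    sig = de["FDR"] < fdr_max
    up = de.index[sig & (de["logFC"] > abs_logfc_min)]
    down = de.index[sig & (de["logFC"] < -abs_logfc_min)]
    return up, down
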