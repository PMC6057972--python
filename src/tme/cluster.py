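"""Graph-based clustering, cluster-enrichment logFC, and gene signatures.

Clustering builds a shared-nearest-neighbor graph in PC space and runs
modularity community detection (Leiden by default, Louvain as a switch) at a
given resolution. Cluster markers use the enrichment statistic

    C[i,j]   = e^N[i,j] - 1
    logFC[i] = log2(mean_{j in K} C[i,j] + eps) - log2(mean_{j not in K} C[i,j] + eps)

with a small pseudocount eps inside both log2 terms, which keeps the value
defined when a gene is absent from one side and preserves the exact
antisymmetry of the two-cluster case. "Expressed" means raw count > 0
throughout the 20%/5% fraction filters.

Signatures for cell types are derived from bulk reference profiles: for each
type, every pairwise comparison against the other types yields a list of
significantly up-regulated genes (FDR-cut, top-k by decreasing fold change),
and the signature is the intersection of those lists. The per-comparison
differential ranking is pluggable; the shipped default is a moderated
t-test on log2-CPM with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .datatypes import BulkCounts, ClusterAssignment, NormalizedMatrix, Signature

LOGFC_EPS = 1e-9


class ParameterError(ValueError):
    pass


@dataclass
class ClusterParams:
    n_neighbors: int = 20
    resolution: float = 0.23
    seed: int = 0
    method: str = "leiden"  # or "louvain"

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ParameterError("n_neighbors must be >= 2")
        if self.resolution <= 0:
            raise ParameterError("resolution must be > 0")


def snn_graph(embedding: np.ndarray, n_neighbors: int) -> ig.Graph:
    """Shared-nearest-neighbor graph: Jaccard overlap of kNN sets as weights."""
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(embedding)
    _, knn = nn.kneighbors(embedding)  # includes self
    neighbor_sets = [set(row) for row in knn]
    edges, weights = [], []
    for i in range(n):
        for j in knn[i]:
            if j <= i:
                continue
            shared = len(neighbor_sets[i] & neighbor_sets[int(j)])
            jac = shared / (2 * n_neighbors - shared)
            if jac > 0:
                edges.append((i, int(j)))
                weights.append(jac)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_cells(embedding: np.ndarray, params: ClusterParams | None = None) -> ClusterAssignment:
    """Cluster cells in PC space; labels 1..k assigned by decreasing cluster size."""
    params = params or ClusterParams()
    n = embedding.shape[0]
    if n < params.n_neighbors:
        raise ParameterError("fewer cells than n_neighbors")
    g = snn_graph(embedding, params.n_neighbors)
    if params.method == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=params.resolution,
            seed=params.seed,
            n_iterations=5,
        )
        membership = np.asarray(part.membership)
    elif params.method == "louvain":
        part = g.community_multilevel(weights="weight", resolution=params.resolution)
        membership = np.asarray(part.membership)
    else:
        raise ParameterError(f"unknown clustering method: {params.method}")

    # relabel 1..k by decreasing size; ties by original community id
    sizes = pd.Series(membership).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[m] for m in membership])
    return ClusterAssignment(
        labels=labels,
        cells=pd.RangeIndex(n),
        resolution=params.resolution,
        seed=params.seed,
        method=params.method,
    )


def _group_logfc(
    C_in_sum: np.ndarray, n_in: int, C_out_sum: np.ndarray, n_out: int, eps: float = LOGFC_EPS
) -> np.ndarray:
    return np.log2(C_in_sum / n_in + eps) - np.log2(C_out_sum / n_out + eps)


def cluster_markers(
    norm: NormalizedMatrix,
    assignment: ClusterAssignment,
    min_frac: float = 0.2,
    eps: float = LOGFC_EPS,
) -> pd.DataFrame:
    """Enrichment logFC of every gene in every cluster vs the rest.

    Keeps genes expressed (count > 0) in at least ``min_frac`` of the
    cluster's cells; rows sorted by decreasing logFC within each cluster,
    ties broken by gene identifier.
    """
    labels = np.asarray(assignment.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two clusters for marker computation")
    C = norm.matrix.copy()
    C.data = np.expm1(C.data)
    expressed = (norm.matrix > 0).astype(np.int64)
    total_sum = np.asarray(C.sum(axis=1)).ravel()
    total_expr = np.asarray(expressed.sum(axis=1)).ravel()
    n_tot = norm.n_cells

    records = []
    for k in sorted(np.unique(labels)):
        in_mask = labels == k
        n_k = int(in_mask.sum())
        C_in = np.asarray(C[:, in_mask].sum(axis=1)).ravel()
        expr_in = np.asarray(expressed[:, in_mask].sum(axis=1)).ravel()
        logfc = _group_logfc(C_in, n_k, total_sum - C_in, n_tot - n_k, eps)
        frac_in = expr_in / n_k
        frac_out = (total_expr - expr_in) / (n_tot - n_k)
        keep = frac_in >= min_frac
        sub = pd.DataFrame(
            {
                "cluster": k,
                "gene": norm.genes[keep],
                "logFC": logfc[keep],
                "frac_in": frac_in[keep],
                "frac_out": frac_out[keep],
            }
        ).sort_values(["logFC", "gene"], ascending=[False, True], kind="stable")
        records.append(sub)
    return pd.concat(records, ignore_index=True)


def condition_contrast(
    norm: NormalizedMatrix,
    cond_a: str,
    cond_b: str,
    top_n: int = 100,
    min_cell_frac: float = 0.05,
    eps: float = LOGFC_EPS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top up/down gene lists for condition A vs B within one cell subset.

    Same logFC machinery as cluster markers with K = cells of condition A.
    Genes must be expressed (count > 0) in at least ``min_cell_frac`` of
    cells in at least one group; groups are per sample when sample labels
    are attached, per condition otherwise. Returns (up, down) tables of
    ``top_n`` rows each, up ranked by decreasing and down by increasing logFC.
    """
    if norm.cell_conditions is None:
        raise ValueError("condition labels required")
    conds = np.asarray(norm.cell_conditions)
    mask_a = conds == cond_a
    mask_b = conds == cond_b
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"conditions {cond_a!r} and {cond_b!r} must both be present")

    expressed = (norm.matrix > 0).astype(np.int64)
    if norm.cell_samples is not None:
        groups = [np.asarray(norm.cell_samples) == s for s in pd.unique(norm.cell_samples)]
    else:
        groups = [mask_a, mask_b]
    frac_ok = np.zeros(norm.n_genes, bool)
    for gmask in groups:
        if gmask.sum() == 0:
            continue
        frac = np.asarray(expressed[:, gmask].sum(axis=1)).ravel() / gmask.sum()
        frac_ok |= frac >= min_cell_frac

    C = norm.matrix.copy()
    C.data = np.expm1(C.data)
    C_a = np.asarray(C[:, mask_a].sum(axis=1)).ravel()
    C_b = np.asarray(C[:, mask_b].sum(axis=1)).ravel()
    logfc = _group_logfc(C_a, int(mask_a.sum()), C_b, int(mask_b.sum()), eps)

    df = pd.DataFrame({"gene": norm.genes, "logFC": logfc})[frac_ok]
    up = df.sort_values(["logFC", "gene"], ascending=[False, True], kind="stable").head(top_n)
    down = df.sort_values(["logFC", "gene"], ascending=[True, True], kind="stable").head(top_n)
    return up.reset_index(drop=True), down.reset_index(drop=True)


def moderated_t_ranker(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame, prior_df: float = 50.0
) -> pd.DataFrame:
    """Default pluggable DE ranker: moderated t-test on log2-CPM, BH FDR.

    Per-gene pooled variances are shrunk toward their grand mean with
    ``prior_df`` prior degrees of freedom (empirical-Bayes moderation in the
    limma style); the t statistic uses the shrunk variance and gains the
    prior degrees of freedom. With the 2-4 replicates typical of reference
    profiles an unmoderated test cannot reach stringent FDR levels, which is
    why moderation is the default. logFC is the log2 ratio of group mean CPM
    (pseudocount 0.5). Returns a DataFrame indexed by gene with columns
    logFC and FDR.
    """
    na, nb = counts_a.shape[1], counts_b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 replicates")
    cpm_a = counts_a * 1e6 / counts_a.sum(axis=0)
    cpm_b = counts_b * 1e6 / counts_b.sum(axis=0)
    logfc = np.log2(cpm_a.mean(axis=1) + 0.5) - np.log2(cpm_b.mean(axis=1) + 0.5)
    # log-CPM with a library-scaled prior count (as in edgeR's cpm(log=TRUE)):
    # a plain log2(CPM + 1) makes a zero-to-one-count jump span several log
    # units in small libraries, wrecking the variance of low-count genes
    prior = 2.0
    la = np.log2((counts_a + prior) * 1e6 / (counts_a.sum(axis=0) + 2 * prior)).values
    lb = np.log2((counts_b + prior) * 1e6 / (counts_b.sum(axis=0) + 2 * prior)).values
    df_resid = na + nb - 2
    var_pool = (la.var(axis=1, ddof=1) * (na - 1) + lb.var(axis=1, ddof=1) * (nb - 1)) / df_resid
    # mean-dependent variance prior: median pooled variance within bins of
    # average log2-CPM, so low-expression genes do not inflate the prior of
    # high-expression ones
    mean_expr = np.concatenate([la, lb], axis=1).mean(axis=1)
    n_bins = 20
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(mean_expr.size, int)
    bins[order] = np.arange(mean_expr.size) * n_bins // mean_expr.size
    var_prior = np.empty(mean_expr.size)
    for b in np.unique(bins):
        members = bins == b
        var_prior[members] = max(np.median(var_pool[members]), 1e-12)
    var_mod = (prior_df * var_prior + df_resid * var_pool) / (prior_df + df_resid)
    se = np.sqrt(var_mod * (1.0 / na + 1.0 / nb))
    t = (la.mean(axis=1) - lb.mean(axis=1)) / np.maximum(se, 1e-300)
    pvals = 2.0 * stats.t.sf(np.abs(t), df=prior_df + df_resid)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"logFC": logfc, "FDR": fdr}, index=counts_a.index)


def derive_signatures(
    reference: BulkCounts,
    de_ranker=moderated_t_ranker,
    fdr: float = 1e-4,
    top_k: int = 200,
    top_n_override: int | None = None,
) -> dict[str, Signature]:
    """Derive one marker signature per reference cell type.

    For cell type T and each other type T', genes with FDR below the cutoff
    and positive logFC are ranked by decreasing logFC and the top ``top_k``
    kept; T's signature is the intersection of all its pairwise lists,
    ordered by decreasing mean logFC. ``top_n_override`` truncates the final
    signature (the short-signature variant used when few reference types are
    available).
    """
    if reference.sample_conditions is None:
        raise ValueError("reference profiles need per-sample cell-type labels")
    types = list(pd.unique(reference.sample_conditions))
    if len(types) < 2:
        raise ValueError("need >= 2 reference cell types")

    cols_by_type = {
        t: reference.counts.loc[:, reference.sample_conditions[reference.sample_conditions == t].index]
        for t in types
    }
    signatures = {}
    for t in types:
        lists = []
        mean_lfc = pd.Series(0.0, index=reference.counts.index)
        for other in types:
            if other == t:
                continue
            de = de_ranker(cols_by_type[t], cols_by_type[other])
            hits = de[(de["FDR"] < fdr) & (de["logFC"] > 0)]
            hits = hits.sort_values(["logFC"], ascending=False, kind="stable").head(top_k)
            lists.append(set(hits.index))
            mean_lfc = mean_lfc.add(de["logFC"], fill_value=0.0)
        common = set.intersection(*lists) if lists else set()
        ordered = sorted(common, key=lambda g: (-mean_lfc[g], g))
        if top_n_override is not None:
            ordered = ordered[:top_n_override]
        signatures[t] = Signature(
            cell_type=t, genes=ordered, fdr=fdr, top_k=top_k, n_lists=len(lists)
        )
    return signatures


def annotate_clusters(
    norm: NormalizedMatrix,
    assignment: ClusterAssignment,
    signatures: dict[str, Signature],
) -> pd.DataFrame:
    """Assign each cluster the cell type whose signature scores highest.

    score(cluster, signature) = mean over signature genes of the per-gene
    z-scored cluster-mean expression; z-scoring is across clusters, so a
    gene contributes how unusually high a cluster expresses it. Returns a
    table with the full score matrix, the argmax type, and the margin to the
    runner-up; ambiguous (all-zero) clusters are flagged.
    """
    if not signatures:
        raise ValueError("need at least one signature")
    labels = np.asarray(assignment.labels)
    clusters = sorted(np.unique(labels))
    means = np.column_stack(
        [np.asarray(norm.matrix[:, labels == k].mean(axis=1)).ravel() for k in clusters]
    )  # genes x clusters
    sd = means.std(axis=1, ddof=0)
    z = np.where(sd[:, None] > 0, (means - means.mean(axis=1)[:, None]) / np.where(sd[:, None] > 0, sd[:, None], 1.0), 0.0)

    rows = []
    for ci, k in enumerate(clusters):
        scores = {}
        for name, sig in signatures.items():
            idx = norm.genes.get_indexer([g for g in sig.genes if g in norm.genes])
            idx = idx[idx >= 0]
            if idx.size == 0:
                warnings.warn(f"signature {name} has no genes in the matrix; skipped")
                continue
            scores[name] = float(z[idx, ci].mean())
        if not scores:
            raise ValueError("no signature overlaps the matrix")
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        best, best_score = ranked[0]
        margin = best_score - ranked[1][1] if len(ranked) > 1 else np.inf
        ambiguous = all(abs(v) < 1e-12 for v in scores.values())
        rows.append(
            {
                "cluster": k,
                "cell_type": "ambiguous" if ambiguous else best,
                "score": best_score,
                "margin": margin,
                **{f"score_{n}": v for n, v in scores.items()},
            }
        )
    return pd.DataFrame(rows)
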