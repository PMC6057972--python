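"""Sub-clustering of a focal cluster and its MST trajectory over centroids.

The focal cluster's cells are re-processed from raw counts (normalization,
scaling, HVG selection and PCA are re-run on the subset, since the subset's
own axes of variation differ from the global ones) and re-clustered at a
finer resolution. Sub-cluster centroids in the subset's PC space are joined
by the minimum spanning tree of their complete Euclidean graph; the tree's
diameter path is reported as the trajectory backbone, each node annotated
with its size and experimental-condition composition. Nodes where no single
condition reaches half the cells are flagged as having dispersed composition.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .cluster import ClusterParams, cluster_cells
from .datatypes import ClusterAssignment, MstTrajectory, SparseCounts
from .qc import HvgParams, compute_covariates, log_normalize, pca_embed, regress_and_scale, select_hvg


def subcluster(
    counts: SparseCounts,
    cell_mask: np.ndarray,
    resolution: float = 0.5,
    seed: int = 0,
    n_neighbors: int = 20,
    n_pcs: int = 25,
    hvg_params: HvgParams | None = None,
    method: str = "leiden",
) -> tuple[ClusterAssignment, np.ndarray]:
    """Re-cluster the cells in ``cell_mask`` from raw counts at finer resolution.

    Returns the sub-cluster assignment and the subset's own PC embedding.
    """
    sub = counts.subset(cell_mask=cell_mask)
    if sub.n_cells < n_neighbors:
        raise ValueError(f"focal cluster has {sub.n_cells} cells < n_neighbors={n_neighbors}")
    norm = log_normalize(sub)
    cov = compute_covariates(sub, norm)
    scaled = regress_and_scale(norm, cov)
    hvg = select_hvg(norm, hvg_params)
    if hvg.sum() < n_pcs:  # small subsets: fall back to the most dispersed genes
        n_pcs = max(2, min(n_pcs, sub.n_cells - 1, sub.n_genes))
        if hvg.sum() < n_pcs:
            order = np.argsort(scaled.var(axis=1))[::-1]
            hvg = np.zeros(sub.n_genes, bool)
            hvg[order[: max(n_pcs, 50)]] = True
    emb = pca_embed(scaled, hvg, n_pcs=min(n_pcs, int(hvg.sum()), sub.n_cells - 1))
    assignment = cluster_cells(
        emb, ClusterParams(n_neighbors=n_neighbors, resolution=resolution, seed=seed, method=method)
    )
    return assignment, emb


def mst_over_centroids(
    assignment: ClusterAssignment,
    embedding: np.ndarray,
    conditions: pd.Series | np.ndarray,
) -> MstTrajectory:
    """Minimum spanning tree of sub-cluster centroids in PC space.

    Centroid = mean PC vector per sub-cluster; edges of the complete graph
    are weighted by Euclidean distance and the MST extracted by Kruskal's
    algorithm with ties broken by lexicographic node-id order. Composition
    comes from the cells' condition labels. A single sub-cluster yields a
    degenerate one-node trajectory with a warning.
    """
    labels = np.asarray(assignment.labels)
    conditions = np.asarray(conditions)
    nodes = sorted(np.unique(labels))
    centroids = {k: embedding[labels == k].mean(axis=0) for k in nodes}
    sizes = {k: int((labels == k).sum()) for k in nodes}
    composition = {}
    for k in nodes:
        vals, cnts = np.unique(conditions[labels == k], return_counts=True)
        composition[k] = {str(v): float(c) / sizes[k] for v, c in zip(vals, cnts)}

    if len(nodes) == 1:
        warnings.warn("single sub-cluster: degenerate one-node trajectory")
        return MstTrajectory(nodes, sizes, composition, centroids, edges=[])

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):  # lexicographic insertion; Kruskal's stable sort
        for v in nodes[i + 1 :]:  # then breaks weight ties by insertion order
            w = float(np.linalg.norm(centroids[u] - centroids[v]))
            g.add_edge(u, v, weight=w)
    mst_edges = [
        (min(u, v), max(u, v), d["weight"])
        for u, v, d in nx.minimum_spanning_edges(g, algorithm="kruskal", data=True)
    ]
    mst_edges.sort()
    return MstTrajectory(nodes, sizes, composition, centroids, edges=mst_edges)


def _farthest(adj: dict[int, list[tuple[int, float]]], start: int) -> tuple[int, float, dict]:
    """Weighted farthest node from start in a tree (DFS); ties -> smallest id."""
    dist = {start: 0.0}
    parent = {start: None}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                parent[v] = u
                stack.append(v)
    best = min(dist, key=lambda n: (-dist[n], n))
    return best, dist[best], parent


def trajectory_report(trajectory: MstTrajectory, dispersed_threshold: float = 0.5) -> dict:
    """Summarize the trajectory: diameter backbone, dominant conditions, flags.

    The backbone is the longest (weighted) path in the MST, found by two
    farthest-node sweeps; ties are broken toward smaller node ids, and the
    backbone is reported with its smaller endpoint first. Each node gets its
    plurality condition; nodes where no condition reaches
    ``dispersed_threshold`` of the cells are flagged dispersed.
    """
    if len(trajectory.node_ids) < 2:
        raise ValueError("trajectory needs >= 2 nodes for a backbone")
    adj: dict[int, list[tuple[int, float]]] = {n: [] for n in trajectory.node_ids}
    for u, v, w in trajectory.edges:
        adj[u].append((v, w))
        adj[v].append((u, w))
    for n in adj:
        adj[n].sort()

    a, _, _ = _farthest(adj, min(trajectory.node_ids))
    b, length, parent = _farthest(adj, a)
    path = [b]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    if path[0] > path[-1]:  # smaller endpoint first
        path = path[::-1]

    nodes = []
    for n in trajectory.node_ids:
        comp = trajectory.composition[n]
        dominant = max(sorted(comp), key=lambda c: comp[c])
        nodes.append(
            {
                "node": int(n),
                "size": trajectory.sizes[n],
                "dominant_condition": dominant,
                "dominant_fraction": comp[dominant],
                "dispersed": comp[dominant] < dispersed_threshold,
            }
        )
    return {
        "backbone": [int(n) for n in path],
        "backbone_length": float(length),
        "nodes": nodes,
    }
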