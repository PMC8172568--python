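"""Dimensionality reduction, SNN graph construction, modularity clustering,
and marker-based cell-type assignment.

The embedding is an exact PCA of centered, unit-scaled highly variable
genes; the neighborhood graph is a shared-nearest-neighbor (SNN) graph with
Jaccard edge weights; clusters come from greedy multi-level (Louvain-style)
modularity optimization with a resolution-scaled null model; cell types are
assigned per cluster from marker gene-set z-scores, and clusters scoring
high for two or more marker sets — typically contamination, e.g. pericyte
clusters carrying endothelial fragments — are excluded.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io import GeneSetCollection
from .preprocess import NormMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "ClusterLabels",
    "pca_embed",
    "build_snn",
    "cluster_modularity",
    "assign_cell_types",
]


@dataclass
class Embedding:
    """Cells x n_pcs coordinates with per-component explained variance."""

    coords: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        ev = self.explained_variance
        if np.any(np.diff(ev) > 1e-10 * max(ev.max(initial=0.0), 1.0)):
            raise ValueError("components must be ordered by decreasing variance")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class ClusterLabels:
    """Per-cell integer cluster IDs, contiguous from 0."""

    labels: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        uniq = np.unique(labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster IDs must be contiguous from 0")
        self.labels = labels

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def pca_embed(norm: NormMatrix, hvg_list, n_pcs: int = 30, scale_clip: float = 10.0) -> Embedding:
    """Exact PCA of the HVG-restricted, centered, unit-scaled expression.

    Each gene is centered and scaled to unit variance (standardized values
    clipped at ``scale_clip``); the embedding is the exact eigendecomposition
    of the cell-cell covariance, computed through an SVD of the standardized
    matrix. Sign convention: the largest-magnitude gene loading of each
    component is positive.
    """
    gene_index = {g: i for i, g in enumerate(norm.gene_ids)}
    rows = [gene_index[g] for g in hvg_list if g in gene_index]
    if len(rows) < len(hvg_list):
        logger.warning("%d HVG(s) absent from matrix", len(hvg_list) - len(rows))
    V = norm.values[rows, :]
    X = (V.toarray() if sp.issparse(V) else np.asarray(V, float)).T  # cells x genes
    n_cells, n_genes = X.shape
    if n_pcs > min(n_genes, n_cells) - 1:
        raise ValueError(
            f"n_pcs = {n_pcs} exceeds min(n_hvg, n_cells) - 1 = "
            f"{min(n_genes, n_cells) - 1}"
        )
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("all genes constant; PCA undefined")
    sd = np.where(sd == 0, 1.0, sd)
    Z = np.clip((X - mean) / sd, -scale_clip, scale_clip)
    Z = Z - Z.mean(axis=0)  # re-center after clipping so PCs are exact
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    ev = S**2 / max(n_cells - 1, 1)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(min(n_pcs, len(S))):
        load = Vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            Vt[j] = -load
            U[:, j] = -U[:, j]
    coords = U[:, :n_pcs] * S[:n_pcs]
    return Embedding(coords=coords, explained_variance=ev[:n_pcs])


def build_snn(embedding: Embedding, k: int = 20, prune: float = 1.0 / 15.0) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    kNN (including self) by Euclidean distance in PC space; the weight of an
    edge is the Jaccard overlap of the two cells' neighbor sets, pruned to
    zero below ``prune``. The returned sparse matrix is symmetric.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = embedding.n_cells
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding.coords)
    ind = nn.kneighbors(return_distance=False)
    # neighbor-set indicator (self included, as in the common SNN recipe)
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([ind, np.arange(n)[:, None]], axis=1).ravel()
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A.data[:] = 1.0
    shared = (A @ A.T).tocoo()  # |N(a) & N(b)|
    inter = shared.data
    jacc = inter / (2 * (k + 1) - inter)
    keep = (jacc >= prune) & (shared.row != shared.col)
    W = sp.csr_matrix(
        (jacc[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )
    W = W.maximum(W.T)  # exact symmetry
    return W


def cluster_modularity(
    graph: sp.csr_matrix, resolution: float = 1.4, seed: int = 0
) -> ClusterLabels:
    """Greedy multi-level modularity optimization on a weighted graph.

    Louvain-style agglomeration with the null model scaled by
    ``resolution``; the node sweep order is fixed by ``seed``, so labels are
    deterministic. A graph with no edges yields singleton clusters (warned).
    """
    n = graph.shape[0]
    coo = sp.triu(sp.csr_matrix(graph), k=1).tocoo()
    if coo.nnz == 0:
        logger.warning("graph has no edges; every cell is its own cluster")
        return ClusterLabels(labels=np.arange(n), resolution=resolution)
    g = ig.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    g.es["weight"] = coo.data.tolist()
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        part = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        _pyrandom.setstate(state)
    labels = np.asarray(part.membership)
    # relabel to contiguous IDs ordered by first occurrence
    _, labels = np.unique(labels, return_inverse=True)
    first = pd.Series(labels).groupby(labels).apply(lambda s: s.index.min())
    order = np.argsort(first.to_numpy())
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(len(order))
    return ClusterLabels(labels=remap[labels], resolution=resolution)


def modularity(graph: sp.csr_matrix, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Resolution-scaled Newman modularity of a partition (for diagnostics)."""
    A = sp.csr_matrix(graph)
    m2 = A.sum()
    if m2 == 0:
        return 0.0
    deg = np.asarray(A.sum(axis=1)).ravel()
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += A[mask][:, mask].sum() / m2
        q -= resolution * (deg[mask].sum() / m2) ** 2
    return float(q)


def assign_cell_types(
    norm: NormMatrix,
    labels: ClusterLabels,
    marker_sets: GeneSetCollection,
    z_threshold: float = 0.5,
):
    """Marker z-score cell-type assignment with ambiguous-cluster exclusion.

    Gene expression is z-scored across all cells; a cluster's score for a
    marker set is the mean over its cells of the mean marker z-score. The
    argmax set is assigned when its score exceeds ``z_threshold``; clusters
    scoring above threshold for two or more sets (mixed identity, e.g.
    endothelial + pericyte) are excluded, as are clusters with no marker
    signal. Returns ``(cluster -> type map, excluded {cluster: reason},
    score table)``.
    """
    names = marker_sets.names()
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap = set(marker_sets.genes(a)) & set(marker_sets.genes(b))
            if overlap:
                raise ValueError(
                    f"marker sets {a!r} and {b!r} overlap: {sorted(overlap)[:5]}"
                )
    gene_index = {g: i for i, g in enumerate(norm.gene_ids)}
    dense = norm.dense()
    mu = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (dense - mu) / sd

    set_scores = {}
    for name in names:
        rows = [gene_index[g] for g in marker_sets.genes(name) if g in gene_index]
        dropped = len(marker_sets.genes(name)) - len(rows)
        if dropped:
            logger.warning("marker set %r: %d gene(s) absent, dropped", name, dropped)
        if not rows:
            raise ValueError(f"marker set {name!r} has no genes in the matrix")
        set_scores[name] = Z[rows, :].mean(axis=0)  # per-cell mean marker z

    clusters = np.unique(labels.labels)
    records = []
    assignment, excluded = {}, {}
    for c in clusters:
        mask = labels.labels == c
        scores = {name: float(set_scores[name][mask].mean()) for name in names}
        high = [name for name in names if scores[name] > z_threshold]
        records.append({"cluster": int(c), **scores, "high_sets": ",".join(high)})
        if len(high) >= 2:
            excluded[int(c)] = f"high expression of multiple marker sets: {high}"
        elif len(high) == 1:
            assignment[int(c)] = high[0]
        else:
            excluded[int(c)] = "no marker signal"
    return assignment, excluded, pd.DataFrame(records)
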