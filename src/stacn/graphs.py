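"""Spatial K-nearest-neighbor graphs with inverse-distance weights.

Each cell is linked to its k nearest Euclidean neighbors with edge
weight 1/r (r the distance), then the graph is symmetrized by the
elementwise maximum so every retained edge keeps its 1/r weight.
Defaults follow platform convention: k = 5 for spot-based 10x arrays,
k = 8 for imaging-based platforms.

Also provides the per-cell topology indices (weighted degree,
shortest-path betweenness with length 1/weight, eigenvector centrality)
used to interpret learned networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SpatialGraph",
    "build_knn_graph",
    "topology_indices",
    "export_graph",
    "PLATFORM_K",
]

PLATFORM_K = {"visium": 5, "imaging": 8}

# above this size exact all-pairs distances give way to a KD-tree
_EXACT_KNN_LIMIT = 20_000


@dataclass
class SpatialGraph:
    """Symmetric nonnegative spatial adjacency with zero diagonal."""

    adjacency: sp.csr_matrix
    k: int
    symmetric: bool = True

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def dense(self) -> np.ndarray:
        return np.asarray(self.adjacency.todense())


def build_knn_graph(coords: np.ndarray, k: int | None = None, platform: str = "custom") -> SpatialGraph:
    """KNN graph on planar coordinates, weights 1/distance, max-symmetrized.

    ``platform`` supplies the conventional k when ``k`` is omitted
    (visium: 5, imaging: 8); ties in distance break by cell index.
    Coinciding coordinates among a cell's selected neighbors are an
    error (jitter the coordinates to resolve).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an n x 2 array")
    if not np.isfinite(coords).all():
        raise ValueError("coords contain non-finite values")
    n = coords.shape[0]
    if k is None:
        if platform not in PLATFORM_K:
            raise ValueError(
                f"platform {platform!r} has no default k; pass k explicitly"
            )
        k = PLATFORM_K[platform]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells n={n}")

    if n <= _EXACT_KNN_LIMIT:
        d2 = (
            np.sum(coords**2, axis=1)[:, None]
            + np.sum(coords**2, axis=1)[None, :]
            - 2 * coords @ coords.T
        )
        np.fill_diagonal(d2, np.inf)
        # stable argsort breaks distance ties by cell index
        nbr = np.argsort(d2, axis=1, kind="stable")[:, :k]
        dist = np.sqrt(np.maximum(np.take_along_axis(d2, nbr, axis=1), 0.0))
    else:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        dist, nbr = nn.kneighbors(coords)
        dist, nbr = dist[:, 1:], nbr[:, 1:]

    zero = np.argwhere(dist == 0)
    if zero.size:
        bad = [(int(i), int(nbr[i, j])) for i, j in zero[:5]]
        raise ValueError(
            f"duplicate coordinates among nearest neighbors (pairs {bad}); "
            "jitter the coordinates to break ties"
        )
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((1.0 / dist.ravel(), (rows, nbr.ravel())), shape=(n, n))
    A = A.maximum(A.T)
    A.setdiag(0)
    A.eliminate_zeros()
    return SpatialGraph(adjacency=A, k=k, symmetric=True)


def export_graph(graph, path, fmt: str = "mtx") -> None:
    """Write a graph as MatrixMarket (``mtx``) or an i/j/weight edge list (``tsv``)."""
    from scipy.io import mmwrite

    A = sp.csr_matrix(graph.adjacency if hasattr(graph, "adjacency") else graph)
    if fmt == "mtx":
        mmwrite(path, A.tocoo())
    elif fmt == "tsv":
        iu = sp.triu(A, k=1).tocoo()
        pd.DataFrame({"i": iu.row, "j": iu.col, "weight": iu.data}).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError("fmt must be 'mtx' or 'tsv'")


def topology_indices(graph) -> pd.DataFrame:
    """Weighted degree, betweenness, and eigenvector centrality per cell.

    Degree is the weighted row sum; betweenness counts shortest paths
    through a cell with edge length 1/weight (unnormalized pair counts);
    eigenvector centrality is the leading eigenvector of the adjacency,
    nonnegative and scaled to unit maximum. On a disconnected graph the
    eigenvector is computed on the largest component, zero elsewhere.
    """
    A = graph.adjacency if hasattr(graph, "adjacency") else graph
    A = sp.csr_matrix(A)
    if (A != A.T).nnz:
        raise ValueError("topology indices require a symmetric graph")
    if A.nnz and A.data.min() < 0:
        raise ValueError("topology indices require nonnegative weights")
    n = A.shape[0]
    degree = np.asarray(A.sum(axis=1)).ravel()

    G = nx.from_scipy_sparse_array(A)
    for _, _, d in G.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    btw = nx.betweenness_centrality(G, normalized=False, weight="length")
    betweenness = np.array([btw[i] for i in range(n)])

    n_comp, comp = sp.csgraph.connected_components(A, directed=False)
    eig = np.zeros(n)
    if n_comp > 1:
        warnings.warn(
            "graph is disconnected; eigenvector centrality computed on the "
            "largest component only"
        )
    sizes = np.bincount(comp)
    main = np.flatnonzero(comp == np.argmax(sizes))
    sub = A[np.ix_(main, main)]
    if main.size == 1:
        eig[main] = 1.0
    else:
        if main.size <= 3:
            vals, vecs = np.linalg.eigh(sub.toarray())
            v = vecs[:, -1]
        else:
            vals, vecs = sp.linalg.eigsh(sub.asfptype(), k=1, which="LA")
            v = vecs[:, 0]
        v = np.abs(v)
        eig[main] = v / v.max()
    return pd.DataFrame(
        {"degree": degree, "betweenness": betweenness, "eigenvector_centrality": eig}
    )
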