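"""Cell affinity graph learning and spatial-domain identification.

The compatible cell features are turned into a sparse symmetric
affinity graph by l1-penalized self-representation (each cell expressed
as a sparse nonnegative-weighted combination of the others) with a
structural KNN pruning, and the graph is partitioned with the Leiden
algorithm under a resolution grid search targeting a requested number
of domains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp

from . import denoise as _denoise
from . import graphs as _graphs
from . import preprocess as _pre

__all__ = [
    "AffinityGraph",
    "DomainAssignment",
    "PipelineResult",
    "learn_affinity",
    "leiden_with_target_k",
    "run_pipeline",
    "RESOLUTION_GRID",
]

# resolution grid used to hit a requested number of domains
RESOLUTION_GRID = np.round(np.arange(0.10, 2.50 + 1e-9, 0.01), 2)


@dataclass
class AffinityGraph:
    """Symmetric nonnegative cell-cell similarity graph, zero diagonal."""

    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency)
        if (abs(A - A.T)).nnz:
            raise ValueError("affinity must be exactly symmetric")
        if A.nnz and A.data.min() < 0:
            raise ValueError("affinity weights must be nonnegative")
        if np.any(A.diagonal() != 0):
            raise ValueError("affinity diagonal must be zero")
        self.adjacency = A

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def dense(self) -> np.ndarray:
        return np.asarray(self.adjacency.todense())


@dataclass
class DomainAssignment:
    """Integer domain label per cell and the resolution that produced it."""

    labels: np.ndarray
    n_domains: int
    resolution: float
    seed: int


@dataclass
class PipelineResult:
    """All intermediates of a full run."""

    assignment: DomainAssignment
    denoise: _denoise.DenoiseResult | None
    affinity: AffinityGraph
    features: np.ndarray
    spatial: _graphs.SpatialGraph
    processed: _pre.SliceData


def _solve_self_representation(F: np.ndarray, alpha: float, l2: float,
                               max_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """FISTA solve of the nonnegative elastic-net self-representation problem.

    Returns the coefficient matrix C >= 0 with zero diagonal minimizing
    0.5||F' - F'C||_F^2 + sum_t thr_t ||C[:,t]||_1 + (l2/2)||C||_F^2,
    thr_t = alpha * (largest off-diagonal gram entry of column t).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if l2 < 0:
        raise ValueError("l2 must be nonnegative")
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    G = F @ F.T  # gram of the cell profiles; gradient is G C - G + l2 C
    Goff = G - np.diag(np.diag(G))
    thr_col = alpha * np.maximum(Goff.max(axis=0), 1e-12)
    L = max(float(np.linalg.eigvalsh(G)[-1]), 1e-12) + l2

    C = np.zeros((n, n))
    Z = C.copy()
    t = 1.0
    step = 1.0 / L
    for _ in range(max_iter):
        grad = G @ Z - G + l2 * Z
        C_new = np.maximum(Z - step * grad - step * thr_col[None, :], 0.0)
        np.fill_diagonal(C_new, 0.0)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        Z = C_new + ((t - 1) / t_new) * (C_new - C)
        np.fill_diagonal(Z, 0.0)
        delta = np.linalg.norm(C_new - C) / max(np.linalg.norm(C), 1e-12)
        C, t = C_new, t_new
        if delta < tol:
            break
    return C


def learn_affinity(F: np.ndarray, alpha: float = 0.3, l2: float = 2.0,
                   knn_prune: int = 30, max_iter: int = 500,
                   tol: float = 1e-8) -> AffinityGraph:
    """Sparse nonnegative self-representation affinity from L2-normalized features.

    Solves, by FISTA with projection onto C >= 0 and a zero diagonal,

        min_C 0.5 ||F' - F' C||_F^2 + sum_t thr_t ||C[:, t]||_1
              + (l2/2) ||C||_F^2

    where the sparsity threshold adapts per cell, ``thr_t = alpha *
    max_j G_jt`` (G the feature gram), so every cell keeps its strongest
    partners regardless of its absolute similarity scale. The
    nonnegativity bars anti-correlated cells from entering the graph and
    the ridge term spreads weight over groups of correlated neighbors
    instead of electing single representatives. The result is
    symmetrized ``(C + C')/2``, each cell's ``knn_prune`` strongest
    neighbors are kept, and the pruned graph is re-symmetrized by
    elementwise maximum.
    """
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    C = _solve_self_representation(F, alpha, l2, max_iter=max_iter, tol=tol)
    Aff = 0.5 * (C + C.T)
    np.fill_diagonal(Aff, 0.0)
    if knn_prune < n - 1:
        keep = np.zeros_like(Aff, dtype=bool)
        order = np.argsort(-Aff, axis=1, kind="stable")[:, :knn_prune]
        np.put_along_axis(keep, order, True, axis=1)
        pruned = np.where(keep, Aff, 0.0)
        Aff = np.maximum(pruned, pruned.T)
    return AffinityGraph(adjacency=sp.csr_matrix(Aff))


def _leiden_once(g: ig.Graph, weights, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=float(resolution),
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def leiden_with_target_k(graph: AffinityGraph, k_target: int, seed: int = 0) -> DomainAssignment:
    """Leiden clustering at the smallest resolution yielding k_target domains.

    Scans resolutions 0.10, 0.11, ..., 2.50 with a fixed seed and
    returns at the first exact match; if no resolution yields exactly
    k_target communities, the closest count wins with a warning.
    """
    if k_target < 1:
        raise ValueError("k_target must be at least 1")
    A = graph.adjacency if isinstance(graph, AffinityGraph) else sp.csr_matrix(graph)
    if A.nnz == 0:
        raise ValueError("affinity graph has no edges")
    iu = sp.triu(A, k=1).tocoo()
    g = ig.Graph(
        n=A.shape[0], edges=list(zip(iu.row.tolist(), iu.col.tolist()))
    )
    weights = iu.data.tolist()

    best = None  # (count distance, resolution, labels, n_comm)
    for res in RESOLUTION_GRID:
        labels = _leiden_once(g, weights, res, seed)
        n_comm = labels.max() + 1
        if n_comm == k_target:
            return DomainAssignment(
                labels=labels, n_domains=int(n_comm), resolution=float(res), seed=seed
            )
        dist = abs(n_comm - k_target)
        if best is None or dist < best[0]:
            best = (dist, float(res), labels, int(n_comm))
    warnings.warn(
        f"no resolution in [0.1, 2.5] yields exactly {k_target} domains; "
        f"returning {best[3]} domains at resolution {best[1]}"
    )
    return DomainAssignment(labels=best[2], n_domains=best[3], resolution=best[1], seed=seed)


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    """Pipeline failure with the originating stage name attached."""


def _raw_expression_network(features: np.ndarray) -> np.ndarray:
    """Un-denoised expression network: rectified cosine similarity of features."""
    norms = np.linalg.norm(features, axis=1, keepdims=True)
    Fn = features / np.where(norms == 0, 1.0, norms)
    S = np.maximum(Fn @ Fn.T, 0.0)
    np.fill_diagonal(S, 0.0)
    return 0.5 * (S + S.T)


def run_pipeline(
    slice_: _pre.SliceData,
    k_target: int,
    pre_cfg: _pre.PreprocessConfig | None = None,
    denoise_cfg: _denoise.DenoiseConfig | None = None,
    k_neighbors: int | None = None,
    platform: str = "visium",
    alpha: float = 0.3,
    l2: float = 2.0,
    knn_prune: int = 30,
    mode: str = "joint",
    seed: int = 0,
) -> PipelineResult:
    """Full run: preprocess, spatial graph, denoise, features, affinity, Leiden.

    ``mode`` selects the feature route: ``joint`` (tensor decomposition
    of both denoised networks — the full method), ``concat`` (per-view
    matrix decompositions, the concatenation ablation), or ``raw``
    (skip denoising; decompose the raw similarity/spatial graphs).
    """
    if mode not in ("joint", "concat", "raw"):
        raise ValueError("mode must be 'joint', 'concat' or 'raw'")
    pre_cfg = pre_cfg or _pre.PreprocessConfig(seed=seed)
    denoise_cfg = denoise_cfg or _denoise.DenoiseConfig(seed=seed)

    with _stage("preprocess"):
        processed = _pre.filter_and_normalize(slice_, pre_cfg)
        processed = _pre.select_hvg(processed, pre_cfg.n_hvg)
    with _stage("spatial_graph"):
        graph = _graphs.build_knn_graph(processed.coords, k=k_neighbors, platform=platform)
    with _stage("preprocess"):
        X = _pre.banksy_augment(processed.dense(), graph, pre_cfg.banksy_mix)
        scores = _pre.pca_reduce(X, pre_cfg.n_pcs, seed=pre_cfg.seed)

    A = graph.dense()
    result = None
    with _stage("denoise"):
        if mode == "raw":
            We, Ws = _raw_expression_network(scores), A
            features = _denoise.features_from_networks(We, Ws, min(denoise_cfg.d, A.shape[0]), joint=True)
        else:
            result = _denoise.admm_solve(scores.T, A, denoise_cfg)
            joint = mode == "joint"
            features = _denoise.features_from_networks(
                result.state.We, result.state.Ws, min(denoise_cfg.d, A.shape[0]), joint=joint
            )
    with _stage("affinity"):
        aff = learn_affinity(features, alpha=alpha, l2=l2, knn_prune=knn_prune)
    with _stage("clustering"):
        assignment = leiden_with_target_k(aff, k_target, seed=seed)
    return PipelineResult(
        assignment=assignment,
        denoise=result,
        affinity=aff,
        features=features,
        spatial=graph,
        processed=processed,
    )
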