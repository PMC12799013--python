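"""Clustering and spatial-coherence metrics.

Agreement with reference labels (ARI, NMI), internal cluster geometry
(silhouette, Davies-Bouldin, separation, compactness) and global
spatial autocorrelation (Moran's I) over a weighted neighbor graph.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn import metrics as _skm

__all__ = [
    "ari",
    "nmi",
    "silhouette_db",
    "morans_i",
    "separation_compactness",
    "metric_report",
]


def _check_lengths(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"label lengths differ: {a.shape[0]} vs {b.shape[0]}")
    return a, b


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index under the permutation model."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(_skm.adjusted_rand_score(a, b))


def nmi(labels_a, labels_b) -> float:
    """Mutual information normalized by the arithmetic mean of the entropies."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(_skm.normalized_mutual_info_score(a, b, average_method="arithmetic"))


def silhouette_db(features, labels) -> dict:
    """Silhouette coefficient and Davies-Bouldin score on Euclidean distances."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette and Davies-Bouldin need at least 2 clusters")
    return {
        "silhouette": float(_skm.silhouette_score(features, labels)),
        "davies_bouldin": float(_skm.davies_bouldin_score(features, labels)),
    }


def morans_i(values, graph, row_standardize: bool = False) -> float:
    """Global Moran's I of per-cell values over a weighted spatial graph.

    I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centered
    values and S0 the total edge weight. A 2-D array of values (an
    embedding) yields the mean of per-dimension I.
    """
    W = graph.adjacency if hasattr(graph, "adjacency") else graph
    W = sp.csr_matrix(W, dtype=float)
    values = np.asarray(values, dtype=float)
    n = W.shape[0]
    if n < 2:
        raise ValueError("Moran's I needs at least 2 cells")
    if values.shape[0] != n:
        raise ValueError("values length does not match graph size")
    if row_standardize:
        rs = np.asarray(W.sum(axis=1)).ravel()
        W = sp.diags(np.where(rs > 0, 1.0 / np.where(rs == 0, 1.0, rs), 0.0)) @ W
    S0 = W.sum()
    if S0 == 0:
        raise ValueError("graph has no edges")

    vals2d = values[:, None] if values.ndim == 1 else values
    out = []
    for j in range(vals2d.shape[1]):
        z = vals2d[:, j] - vals2d[:, j].mean()
        denom = float(z @ z)
        if denom == 0:
            raise ValueError("Moran's I is undefined for constant values")
        out.append(n / S0 * float(z @ (W @ z)) / denom)
    return float(np.mean(out))


def separation_compactness(features, labels) -> dict:
    """Mean inter-centroid distance and mean within-domain distance to centroid."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("separation is undefined for a single domain")
    centroids = np.stack([features[labels == u].mean(axis=0) for u in uniq])
    pair = [
        np.linalg.norm(centroids[i] - centroids[j])
        for i in range(len(uniq))
        for j in range(i + 1, len(uniq))
    ]
    within = np.concatenate(
        [
            np.linalg.norm(features[labels == u] - centroids[i], axis=1)
            for i, u in enumerate(uniq)
        ]
    )
    return {"separation": float(np.mean(pair)), "compactness": float(np.mean(within))}


def metric_report(
    predicted,
    truth=None,
    features=None,
    graph=None,
) -> dict:
    """All metrics computable from the supplied inputs, as a flat dict."""
    report: dict[str, float] = {}
    predicted = np.asarray(predicted)
    if truth is not None:
        report["ari"] = ari(truth, predicted)
        report["nmi"] = nmi(truth, predicted)
    if features is not None and len(np.unique(predicted)) >= 2:
        report.update(silhouette_db(features, predicted))
        report.update(separation_compactness(features, predicted))
    if graph is not None and features is not None:
        report["morans_i"] = morans_i(features, graph)
    return report
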