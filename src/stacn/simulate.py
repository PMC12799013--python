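"""Synthetic domain-structured slices and subspace-structured matrices.

The slice generator emulates the ingredients of SRT data that the
method exploits: spots on a regular grid, contiguous spatial domains,
domain-specific marker genes, over-dispersed counts (log-normal-Poisson
cascade) and dropout. The subspace generator plants columns in
independent low-dimensional subspaces, the regime in which
self-representation learning provably recovers block structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from .preprocess import SliceData

__all__ = [
    "SyntheticSpec",
    "generate_slice",
    "generate_subspace_data",
    "write_slice_fixtures",
]

# baseline log-rate distribution for non-marker signal
_BASE_LOG_MEAN = float(np.log(2.0))
_BASE_LOG_SD = 0.3


@dataclass
class SyntheticSpec:
    """Conditions of a simulated slice.

    marker_lift is the log-scale mean shift of a domain's marker genes
    inside that domain; noise_sd the per-entry log-normal noise;
    dropout_rate the probability an observed count is zeroed.
    """

    grid_shape: tuple[int, int] = (20, 20)
    n_domains: int = 4
    n_genes: int = 200
    n_markers_per_domain: int = 10
    marker_lift: float = 1.0
    noise_sd: float = 0.3
    dropout_rate: float = 0.2
    layout: str = "bands"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 2:
            raise ValueError("need at least 2 domains")
        if self.n_markers_per_domain * self.n_domains > self.n_genes:
            raise ValueError("more marker genes requested than genes available")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.layout not in ("bands", "blocks", "voronoi"):
            raise ValueError("layout must be bands, blocks or voronoi")
        rows, cols = self.grid_shape
        if rows * cols < self.n_domains:
            raise ValueError("grid too small for the requested domains")


def _assign_domains(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    if spec.layout == "bands":
        return np.minimum(
            (rr * spec.n_domains) // rows, spec.n_domains - 1
        ).astype(int)
    if spec.layout == "blocks":
        nb_r = int(np.floor(np.sqrt(spec.n_domains)))
        while spec.n_domains % nb_r:
            nb_r -= 1
        nb_c = spec.n_domains // nb_r
        br = np.minimum((rr * nb_r) // rows, nb_r - 1)
        bc = np.minimum((cc * nb_c) // cols, nb_c - 1)
        return (br * nb_c + bc).astype(int)
    # voronoi: nearest of n_domains random centers
    centers = np.column_stack(
        [rng.uniform(0, rows, spec.n_domains), rng.uniform(0, cols, spec.n_domains)]
    )
    pts = np.column_stack([rr, cc]).astype(float)
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).astype(int)


def generate_slice(spec: SyntheticSpec | None = None) -> SliceData:
    """Simulate one slice on a regular grid with planted domain labels.

    Counts follow a log-normal-Poisson cascade: per-gene baseline
    log-rates, a marker_lift shift for each domain's marker genes inside
    that domain, per-entry Gaussian log-noise, Poisson sampling, then
    independent dropout. Deterministic given the seed.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    n = rows * cols
    labels = _assign_domains(spec, rng)

    base = rng.normal(_BASE_LOG_MEAN, _BASE_LOG_SD, size=spec.n_genes)
    lift = np.zeros((spec.n_domains, spec.n_genes))
    for d in range(spec.n_domains):
        markers = np.arange(
            d * spec.n_markers_per_domain, (d + 1) * spec.n_markers_per_domain
        )
        lift[d, markers] = spec.marker_lift

    log_rate = base[None, :] + lift[labels]
    if spec.noise_sd > 0:
        log_rate = log_rate + rng.normal(0.0, spec.noise_sd, size=(n, spec.n_genes))
    counts = rng.poisson(np.exp(log_rate)).astype(np.int64)
    if spec.dropout_rate > 0:
        counts[rng.random((n, spec.n_genes)) < spec.dropout_rate] = 0

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
    return SliceData(
        counts=counts,
        gene_ids=[f"gene_{j:04d}" for j in range(spec.n_genes)],
        cell_ids=[f"cell_{i:04d}" for i in range(n)],
        coords=coords,
        labels=labels,
    )


def generate_subspace_data(
    n_per_cluster: int,
    n_clusters: int,
    ambient_dim: int,
    sub_dim: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Columns drawn from independent random low-dimensional subspaces.

    Returns a feature x cell matrix with unit-norm clean columns plus
    Gaussian noise, and the planted cluster label per column.
    """
    if sub_dim >= ambient_dim:
        raise ValueError("sub_dim must be smaller than ambient_dim")
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for c in range(n_clusters):
        basis, _ = np.linalg.qr(rng.normal(size=(ambient_dim, sub_dim)))
        coeff = rng.normal(size=(sub_dim, n_per_cluster))
        block = basis @ coeff
        block /= np.linalg.norm(block, axis=0, keepdims=True)
        cols.append(block)
        labels.extend([c] * n_per_cluster)
    D = np.hstack(cols)
    if noise_sd > 0:
        D = D + rng.normal(0.0, noise_sd, size=D.shape)
    return D, np.asarray(labels)


def write_slice_fixtures(slice_: SliceData, outdir) -> dict[str, Path]:
    """Write a slice in the formats the reader consumes.

    Emits matrix.mtx (cells x genes), barcodes.tsv, features.tsv,
    coords.csv (barcode,x,y) and, when labels exist, labels.csv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "matrix.mtx",
        "barcodes": outdir / "barcodes.tsv",
        "features": outdir / "features.tsv",
        "coords": outdir / "coords.csv",
    }
    mmwrite(paths["counts"], sp.coo_matrix(slice_.counts))
    pd.Series(slice_.cell_ids).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    pd.Series(slice_.gene_ids).to_csv(paths["features"], sep="\t", index=False, header=False)
    pd.DataFrame(
        {"barcode": slice_.cell_ids, "x": slice_.coords[:, 0], "y": slice_.coords[:, 1]}
    ).to_csv(paths["coords"], index=False)
    if slice_.labels is not None:
        paths["labels"] = outdir / "labels.csv"
        pd.DataFrame({"barcode": slice_.cell_ids, "domain": slice_.labels}).to_csv(
            paths["labels"], index=False
        )
    return paths
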