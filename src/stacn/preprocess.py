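"""Reading and preprocessing of spatially resolved transcriptomics slices.

A slice is a cells x genes count matrix with per-cell planar coordinates.
The preprocessing chain mirrors common single-cell practice: drop genes
expressed in fewer than a minimum number of cells, scale every cell to
the median library size, log1p-transform, select highly variable genes
by binned dispersion, optionally augment each cell's profile with the
weighted mean profile of its spatial neighbors, and reduce with PCA.

Cells are rows everywhere at this layer; the solver transposes to its
feature x cell convention internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

__all__ = [
    "SliceData",
    "PreprocessConfig",
    "read_slice",
    "filter_and_normalize",
    "select_hvg",
    "banksy_augment",
    "pca_reduce",
    "stack_slices",
]


@dataclass
class SliceData:
    """One tissue slice: counts (cells x genes), ids, coordinates, labels.

    ``counts`` may hold raw nonnegative integers or, after
    :func:`filter_and_normalize`, real-valued normalized expression.
    ``batch`` records slice of origin after :func:`stack_slices`.
    """

    counts: sp.spmatrix | np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    coords: np.ndarray
    labels: np.ndarray | None = None
    batch: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} matrix columns")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords must be {n} x 2, got {self.coords.shape}")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids are not unique")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene ids are not unique")
        if self.dense().size and self.dense().min() < 0:
            raise ValueError("counts contain negative entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length does not match cell count")
        if self.batch is not None:
            self.batch = np.asarray(self.batch)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)


@dataclass
class PreprocessConfig:
    """Preprocessing knobs with field-standard defaults.

    min_cells_per_gene=10 and n_hvg=3000 follow common SRT practice;
    banksy_mix is the fraction of variance given to the spatial
    neighbor-mean augmentation (0 disables it).
    """

    min_cells_per_gene: int = 10
    n_hvg: int = 3000
    banksy_mix: float = 0.2
    n_pcs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.banksy_mix < 1:
            raise ValueError("banksy_mix must lie in [0, 1)")
        if self.min_cells_per_gene < 0 or self.n_hvg < 1 or self.n_pcs < 1:
            raise ValueError("config values must be positive")


def _read_mtx_counts(counts_path: Path) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """MatrixMarket counts + barcodes/features TSV sidecars in the same directory.

    On-disk orientation may be cells x genes or the 10x genes x cells
    convention; the sidecar lengths disambiguate.
    """
    mat = sp.csr_matrix(mmread(counts_path))
    folder = counts_path.parent
    barcodes_file = None
    features_file = None
    for cand in ("barcodes.tsv", "barcodes.txt"):
        if (folder / cand).exists():
            barcodes_file = folder / cand
    for cand in ("features.tsv", "genes.tsv", "features.txt"):
        if (folder / cand).exists():
            features_file = folder / cand
    if barcodes_file is None or features_file is None:
        raise FileNotFoundError(
            f"MTX sidecars (barcodes.tsv, features.tsv) not found next to {counts_path}"
        )
    barcodes = pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str).tolist()
    features = pd.read_csv(features_file, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape == (len(barcodes), len(features)):
        pass
    elif mat.shape == (len(features), len(barcodes)):
        mat = sp.csr_matrix(mat.T)
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {len(barcodes)} barcodes x "
            f"{len(features)} features nor its transpose"
        )
    return mat, barcodes, features


def _read_dense_counts(counts_path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    sep = "\t" if counts_path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(counts_path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float), df.index.astype(str).tolist(), df.columns.astype(str).tolist()


def _read_coords_table(coords_path: Path) -> pd.DataFrame:
    """Simple coordinates table: barcode,x,y with header, or two bare columns."""
    sep = "\t" if coords_path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(coords_path, sep=sep)
    numeric = df.select_dtypes(include=[np.number])
    if df.shape[1] == 2 and numeric.shape[1] == 2:
        return pd.DataFrame({"barcode": None, "x": df.iloc[:, 0], "y": df.iloc[:, 1]})
    if df.shape[1] < 3:
        raise ValueError(
            f"coordinates table {coords_path} needs (barcode, x, y) columns or two numeric columns"
        )
    return pd.DataFrame(
        {
            "barcode": df.iloc[:, 0].astype(str),
            "x": pd.to_numeric(df.iloc[:, 1]),
            "y": pd.to_numeric(df.iloc[:, 2]),
        }
    )


_TENX_COLS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def _read_tenx_positions(coords_path: Path) -> pd.DataFrame:
    """10x tissue_positions dialect; keeps in-tissue spots, prefers pixel columns."""
    first = pd.read_csv(coords_path, nrows=1, header=None)
    has_header = str(first.iloc[0, 0]).strip().lower() == "barcode"
    df = pd.read_csv(coords_path, header=0 if has_header else None)
    if df.shape[1] < 4:
        raise ValueError(f"10x positions table {coords_path} has too few columns")
    df.columns = _TENX_COLS[: df.shape[1]] + list(df.columns[len(_TENX_COLS):])
    df["barcode"] = df["barcode"].astype(str)
    df = df[df["in_tissue"].astype(int) == 1]
    if "pxl_row_in_fullres" in df.columns and "pxl_col_in_fullres" in df.columns:
        x, y = df["pxl_col_in_fullres"], df["pxl_row_in_fullres"]
    else:
        x, y = df["array_col"], df["array_row"]
    return pd.DataFrame(
        {"barcode": df["barcode"], "x": pd.to_numeric(x), "y": pd.to_numeric(y)}
    )


def read_slice(
    counts_path, coords_path, format: str = "mtx_triplet", labels_path=None
) -> SliceData:
    """Read one slice from disk, aligning coordinate rows to count-matrix cells.

    ``format`` selects the dialect: ``mtx_triplet`` (MatrixMarket counts
    with barcode/feature sidecars, simple coords table),
    ``dense_delimited`` (header = genes, index = cells), or
    ``tenx_positions`` (MTX counts, 10x tissue-positions coordinates;
    out-of-tissue spots are dropped).
    """
    counts_path, coords_path = Path(counts_path), Path(coords_path)
    for p in (counts_path, coords_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    if format == "dense_delimited":
        mat, cells, genes = _read_dense_counts(counts_path)
    elif format in ("mtx_triplet", "tenx_positions"):
        mat, cells, genes = _read_mtx_counts(counts_path)
    else:
        raise ValueError(
            f"unknown format {format!r}; tried none of mtx_triplet, dense_delimited, tenx_positions"
        )

    if format == "tenx_positions":
        pos = _read_tenx_positions(coords_path)
    else:
        pos = _read_coords_table(coords_path)

    if pos["barcode"].isna().all():
        if len(pos) != len(cells):
            raise ValueError(
                f"coordinates table has {len(pos)} rows for {len(cells)} cells and no barcodes"
            )
        coords = pos[["x", "y"]].to_numpy(dtype=float)
        keep_cells, keep_idx = cells, np.arange(len(cells))
    else:
        lookup = {b: i for i, b in enumerate(pos["barcode"])}
        if format == "tenx_positions":
            # positions define the in-tissue subset; drop cells absent from it
            keep_idx = np.array([i for i, b in enumerate(cells) if b in lookup], dtype=int)
            if keep_idx.size == 0:
                raise ValueError("no count-matrix barcode matches the positions table")
            keep_cells = [cells[i] for i in keep_idx]
        else:
            missing = [b for b in cells if b not in lookup]
            if missing:
                raise ValueError(f"barcode {missing[0]!r} missing from coordinates table")
            keep_idx = np.arange(len(cells))
            keep_cells = cells
        coords = pos[["x", "y"]].to_numpy(dtype=float)[
            [lookup[b] for b in keep_cells]
        ]

    mat = mat[keep_idx]
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path)
        lab_lookup = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1]))
        missing = [b for b in keep_cells if b not in lab_lookup]
        if missing:
            raise ValueError(f"barcode {missing[0]!r} missing from labels table")
        labels = np.array([lab_lookup[b] for b in keep_cells])
    return SliceData(counts=mat, gene_ids=genes, cell_ids=list(keep_cells), coords=coords, labels=labels)


def filter_and_normalize(slice_: SliceData, cfg: PreprocessConfig | None = None) -> SliceData:
    """Drop rarely expressed genes, scale cells to the median library size, log1p.

    Genes expressed (count > 0) in fewer than ``cfg.min_cells_per_gene``
    cells are removed; each cell's counts are then scaled so its library
    size equals the median library size over cells, and log1p-transformed.
    """
    cfg = cfg or PreprocessConfig()
    X = slice_.dense()
    n_cells_expr = (X > 0).sum(axis=0)
    keep = np.asarray(n_cells_expr >= cfg.min_cells_per_gene).ravel()
    if not keep.any():
        raise ValueError(
            f"all {slice_.n_genes} genes are expressed in fewer than "
            f"{cfg.min_cells_per_gene} cells"
        )
    X = X[:, keep]
    lib = X.sum(axis=1)
    target = float(np.median(lib))
    scale = np.where(lib > 0, target / np.where(lib == 0, 1.0, lib), 0.0)
    X = np.log1p(X * scale[:, None])
    return replace(
        slice_,
        counts=X,
        gene_ids=[g for g, k in zip(slice_.gene_ids, keep) if k],
    )


def _binned_dispersion(X: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Within-mean-bin z-scored dispersion (variance / mean); 0-dispersion genes -> -inf."""
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean == 0, 1.0, mean), 0.0)
    bins = pd.cut(mean, bins=n_bins, labels=False, duplicates="drop")
    bins = np.nan_to_num(np.asarray(bins, dtype=float), nan=0).astype(int)
    norm = np.empty_like(disp)
    for b in np.unique(bins):
        in_bin = bins == b
        mu, sd = disp[in_bin].mean(), disp[in_bin].std()
        norm[in_bin] = (disp[in_bin] - mu) / (sd if sd > 0 else 1.0)
    norm[disp == 0] = -np.inf
    return norm


def select_hvg(slice_: SliceData, n_hvg: int = 3000) -> SliceData:
    """Restrict to the highly variable genes by binned-dispersion ranking.

    Dispersion is variance/mean of the normalized values, z-scored within
    20 mean bins; ties break by gene order. If fewer genes exist than
    requested, all are kept with a warning.
    """
    X = slice_.dense()
    if slice_.n_genes <= n_hvg:
        warnings.warn(
            f"only {slice_.n_genes} genes available for n_hvg={n_hvg}; keeping all"
        )
        return slice_
    score = _binned_dispersion(X)
    # stable sort on negated score keeps gene order among ties
    order = np.argsort(-score, kind="stable")[:n_hvg]
    order = np.sort(order)  # preserve original gene order in output
    return replace(
        slice_,
        counts=X[:, order],
        gene_ids=[slice_.gene_ids[i] for i in order],
    )


def banksy_augment(X: np.ndarray, A, mix: float) -> np.ndarray:
    """Augment each cell's features with its spatial neighbor-mean profile.

    Returns ``[sqrt(1-mix) * X, sqrt(mix) * N @ X]`` where N is the
    row-normalized neighbor-weight matrix of A, doubling the feature
    count. ``mix`` is the variance fraction assigned to the neighborhood
    term; mix = 0 keeps all pairwise distances of X.
    """
    if not 0 <= mix < 1:
        raise ValueError("mix must lie in [0, 1)")
    X = np.asarray(X, dtype=float)
    if mix == 0:
        return np.hstack([X, np.zeros_like(X)])
    A = A.adjacency if hasattr(A, "adjacency") else A
    A = sp.csr_matrix(A)
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    isolated = np.where(rowsum == 0)[0]
    if isolated.size:
        raise ValueError(
            f"cells with no spatial neighbors cannot be augmented (mix>0): "
            f"{isolated.tolist()[:10]}"
        )
    N = sp.diags(1.0 / rowsum) @ A
    return np.hstack([np.sqrt(1 - mix) * X, np.sqrt(mix) * (N @ X)])


def pca_reduce(X: np.ndarray, n_pcs: int, seed: int = 0) -> np.ndarray:
    """Centered PCA scores with a deterministic sign convention.

    Components are orientated so that each one's largest-magnitude
    loading is positive; the decomposition is an exact SVD, so ``seed``
    does not alter the result (kept for interface uniformity).
    """
    X = np.asarray(X, dtype=float)
    n, f = X.shape
    if n_pcs > min(n, f):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(n, features)={min(n, f)}")
    Xc = X - X.mean(axis=0)
    U, s, Vh = np.linalg.svd(Xc, full_matrices=False)
    signs = np.sign(Vh[np.arange(Vh.shape[0]), np.argmax(np.abs(Vh), axis=1)])
    signs[signs == 0] = 1.0
    return (U[:, :n_pcs] * s[:n_pcs]) * signs[:n_pcs]


def stack_slices(slices: list[SliceData]) -> SliceData:
    """Vertically stack slices over their shared genes (no spatial alignment).

    Expression values of shared genes are preserved exactly; a
    slice-of-origin label is carried per cell, and cell ids are prefixed
    with the slice index when needed to stay unique.
    """
    if len(slices) < 2:
        raise ValueError("need at least two slices to stack")
    shared = set(slices[0].gene_ids)
    for s in slices[1:]:
        shared &= set(s.gene_ids)
    if not shared:
        raise ValueError("slices share no genes")
    genes = [g for g in slices[0].gene_ids if g in shared]

    blocks, coords, ids, batch = [], [], [], []
    labels: list | None = []
    for i, s in enumerate(slices):
        idx = [s.gene_ids.index(g) for g in genes]
        blocks.append(s.dense()[:, idx])
        coords.append(s.coords)
        ids.extend(s.cell_ids)
        batch.extend([i] * s.n_cells)
        if labels is not None and s.labels is not None:
            labels.extend(list(s.labels))
        else:
            labels = None
    if len(set(ids)) != len(ids):
        ids = [
            f"{b}-{c}"
            for b, c in zip(batch, ids)
        ]
    return SliceData(
        counts=np.vstack(blocks),
        gene_ids=genes,
        cell_ids=ids,
        coords=np.vstack(coords),
        labels=np.array(labels) if labels is not None else None,
        batch=np.array(batch),
    )
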