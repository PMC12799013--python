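"""Reader and preprocessing-chain behavior on toy matrices and written fixtures."""

import numpy as np
import pandas as pd
import pytest

from stacn.preprocess import (
    PreprocessConfig,
    SliceData,
    banksy_augment,
    filter_and_normalize,
    pca_reduce,
    read_slice,
    select_hvg,
    stack_slices,
)
from stacn.graphs import build_knn_graph
from stacn.simulate import SyntheticSpec, generate_slice, write_slice_fixtures


def toy_slice(counts, coords=None, labels=None):
    counts = np.asarray(counts)
    n, m = counts.shape
    return SliceData(
        counts=counts,
        gene_ids=[f"g{j}" for j in range(m)],
        cell_ids=[f"c{i}" for i in range(n)],
        coords=coords if coords is not None else np.column_stack([np.arange(n), np.zeros(n)]),
        labels=labels,
    )


class TestSliceData:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            toy_slice([[1, -2], [0, 1]])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SliceData(
                counts=np.ones((2, 2)),
                gene_ids=["g", "g"],
                cell_ids=["a", "b"],
                coords=np.zeros((2, 2)),
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="coords"):
            SliceData(
                counts=np.ones((2, 2)),
                gene_ids=["g1", "g2"],
                cell_ids=["a", "b"],
                coords=np.zeros((3, 2)),
            )


class TestReadSlice:
    def test_mtx_round_trip_alignment(self, tmp_path, small_slice):
        paths = write_slice_fixtures(small_slice, tmp_path)
        sl = read_slice(paths["counts"], paths["coords"], format="mtx_triplet",
                        labels_path=paths["labels"])
        assert sl.n_cells == small_slice.n_cells
        assert sl.gene_ids == small_slice.gene_ids
        assert np.array_equal(sl.dense(), small_slice.dense())
        assert np.array_equal(sl.coords, small_slice.coords)
        assert np.array_equal(sl.labels, small_slice.labels)

    def test_coords_matched_by_barcode_not_order(self, tmp_path, small_slice):
        paths = write_slice_fixtures(small_slice, tmp_path)
        df = pd.read_csv(paths["coords"])
        df_shuffled = df.sample(frac=1.0, random_state=1)
        df_shuffled.to_csv(paths["coords"], index=False)
        sl = read_slice(paths["counts"], paths["coords"], format="mtx_triplet")
        assert np.array_equal(sl.coords, small_slice.coords)

    def test_missing_barcode_named_in_error(self, tmp_path, small_slice):
        paths = write_slice_fixtures(small_slice, tmp_path)
        df = pd.read_csv(paths["coords"])
        dropped = df.iloc[0, 0]
        df.iloc[1:].to_csv(paths["coords"], index=False)
        with pytest.raises(ValueError, match=str(dropped)):
            read_slice(paths["counts"], paths["coords"], format="mtx_triplet")

    def test_tenx_positions_drops_out_of_tissue(self, tmp_path, small_slice):
        paths = write_slice_fixtures(small_slice, tmp_path)
        pos = pd.DataFrame(
            {
                "barcode": small_slice.cell_ids,
                "in_tissue": [1] * (small_slice.n_cells - 3) + [0, 0, 0],
                "array_row": small_slice.coords[:, 1].astype(int),
                "array_col": small_slice.coords[:, 0].astype(int),
                "pxl_row_in_fullres": small_slice.coords[:, 1] * 100,
                "pxl_col_in_fullres": small_slice.coords[:, 0] * 100,
            }
        )
        pos_path = tmp_path / "tissue_positions.csv"
        pos.to_csv(pos_path, index=False)
        sl = read_slice(paths["counts"], pos_path, format="tenx_positions")
        assert sl.n_cells == small_slice.n_cells - 3
        # pixel columns preferred over array columns
        assert np.allclose(sl.coords[:, 0], small_slice.coords[:-3, 0] * 100)

    def test_dense_delimited(self, tmp_path):
        df = pd.DataFrame(
            [[1, 0, 2], [0, 3, 1]], index=["c0", "c1"], columns=["g0", "g1", "g2"]
        )
        cpath = tmp_path / "counts.csv"
        df.to_csv(cpath)
        pd.DataFrame({"barcode": ["c0", "c1"], "x": [0.0, 1.0], "y": [0.0, 0.0]}).to_csv(
            tmp_path / "coords.csv", index=False
        )
        sl = read_slice(cpath, tmp_path / "coords.csv", format="dense_delimited")
        assert sl.n_cells == 2 and sl.gene_ids == ["g0", "g1", "g2"]

    def test_unknown_format_error_names_dialects(self, tmp_path):
        (tmp_path / "x.mtx").write_text("")
        (tmp_path / "c.csv").write_text("")
        with pytest.raises(ValueError, match="mtx_triplet"):
            read_slice(tmp_path / "x.mtx", tmp_path / "c.csv", format="weird")


class TestFilterNormalize:
    def test_rare_gene_removed_at_threshold(self):
        counts = np.zeros((100, 2))
        counts[:9, 0] = 1  # expressed in 9 cells only
        counts[:, 1] = 1
        out = filter_and_normalize(toy_slice(counts), PreprocessConfig(min_cells_per_gene=10))
        assert out.gene_ids == ["g1"]

    def test_median_cell_gets_pure_log1p(self):
        counts = np.array([[1, 1], [2, 2], [4, 4]])
        out = filter_and_normalize(toy_slice(counts), PreprocessConfig(min_cells_per_gene=1))
        assert np.allclose(out.dense()[1], np.log1p([2, 2]))

    def test_matches_hand_computation(self):
        counts = np.abs(np.arange(20).reshape(5, 4)) + 1
        out = filter_and_normalize(toy_slice(counts), PreprocessConfig(min_cells_per_gene=1))
        lib = counts.sum(axis=1)
        ref = np.log1p(counts * (np.median(lib) / lib)[:, None])
        assert np.allclose(out.dense(), ref)

    def test_all_genes_filtered_raises(self):
        with pytest.raises(ValueError, match="fewer than"):
            filter_and_normalize(toy_slice(np.ones((3, 2))), PreprocessConfig(min_cells_per_gene=5))

    def test_idempotent_on_gene_set(self, small_slice):
        cfg = PreprocessConfig(min_cells_per_gene=10)
        once = filter_and_normalize(small_slice, cfg)
        # a second pass filters nothing: normalized values are positive where counts were
        again = filter_and_normalize(once, cfg)
        assert again.gene_ids == once.gene_ids


class TestSelectHVG:
    def test_constant_gene_never_selected(self, rng):
        X = rng.normal(2.0, 1.0, size=(50, 10)) ** 2
        X[:, 3] = 5.0  # constant
        sl = toy_slice(X)
        out = select_hvg(sl, 5)
        assert "g3" not in out.gene_ids

    def test_matches_bruteforce_ranking(self, rng):
        X = np.abs(rng.normal(1.0, 1.0, size=(40, 20)))
        sl = toy_slice(X)
        out = select_hvg(sl, 5)
        # independent oracle: same binned dispersion computed from scratch
        mean, var = X.mean(0), X.var(0)
        disp = np.where(mean > 0, var / np.where(mean == 0, 1, mean), 0)
        bins = pd.cut(mean, bins=20, labels=False, duplicates="drop")
        z = np.empty_like(disp)
        for b in np.unique(bins):
            m = bins == b
            sd = disp[m].std()
            z[m] = (disp[m] - disp[m].mean()) / (sd if sd > 0 else 1.0)
        z[disp == 0] = -np.inf
        expect = {f"g{i}" for i in np.argsort(-z, kind="stable")[:5]}
        assert set(out.gene_ids) == expect

    def test_fewer_genes_keeps_all_with_warning(self, rng):
        sl = toy_slice(np.abs(rng.normal(size=(10, 4))))
        with pytest.warns(UserWarning, match="keeping all"):
            out = select_hvg(sl, 3000)
        assert out.n_genes == 4


class TestBanksyAugment:
    def test_mix_zero_preserves_distances(self, rng):
        X = rng.normal(size=(8, 5))
        out = banksy_augment(X, np.zeros((8, 8)), 0.0)
        assert out.shape == (8, 10)
        d_in = np.linalg.norm(X[:, None] - X[None], axis=2)
        d_out = np.linalg.norm(out[:, None] - out[None], axis=2)
        assert np.allclose(d_in, d_out)

    def test_single_neighbor_block(self, rng):
        X = rng.normal(size=(3, 4))
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 2.0
        A[1, 2] = A[2, 1] = 1.0
        out = banksy_augment(X, A, 0.25)
        # cell 0 has the single neighbor 1
        assert np.allclose(out[0, 4:], np.sqrt(0.25) * X[1])

    def test_matches_bruteforce_weighted_mean(self, rng):
        X = rng.normal(size=(6, 3))
        A = rng.uniform(0, 1, (6, 6))
        A = np.triu(A, 1)
        A = A + A.T
        mix = 0.4
        out = banksy_augment(X, A, mix)
        for i in range(6):
            ref = (A[i][:, None] * X).sum(0) / A[i].sum()
            assert np.allclose(out[i, 3:], np.sqrt(mix) * ref)
        assert np.allclose(out[:, :3], np.sqrt(1 - mix) * X)

    def test_isolated_cell_error_lists_cells(self, rng):
        X = rng.normal(size=(4, 2))
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            banksy_augment(X, A, 0.2)


class TestPCAReduce:
    def test_planar_data_exact(self, rng):
        basis = rng.normal(size=(2, 5))
        X = rng.normal(size=(30, 2)) @ basis
        scores = pca_reduce(X, 2)
        # reconstruction from 2 PCs is exact for rank-2 data
        Xc = X - X.mean(0)
        U, s, Vh = np.linalg.svd(Xc, full_matrices=False)
        assert s[2:].max() < 1e-10
        assert np.allclose(np.linalg.norm(scores, axis=1), np.linalg.norm(Xc, axis=1))

    def test_full_rank_preserves_distances(self, rng):
        X = rng.normal(size=(10, 4))
        scores = pca_reduce(X, 4)
        d_in = np.linalg.norm(X[:, None] - X[None], axis=2)
        d_out = np.linalg.norm(scores[:, None] - scores[None], axis=2)
        assert np.allclose(d_in, d_out)

    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(8, 4))
        scores = pca_reduce(X, 3)
        Xc = X - X.mean(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        ref = Xc @ evecs[:, order[:3]]
        # compare up to sign per component
        for j in range(3):
            assert np.allclose(scores[:, j], ref[:, j], atol=1e-8) or np.allclose(
                scores[:, j], -ref[:, j], atol=1e-8
            )

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(9, 5))
        assert np.array_equal(pca_reduce(X, 3), pca_reduce(X, 3))

    def test_n_pcs_too_large_raises(self, rng):
        with pytest.raises(ValueError, match="n_pcs"):
            pca_reduce(rng.normal(size=(5, 3)), 4)


class TestStackSlices:
    def test_counts_and_gene_intersection(self, small_slice):
        spec2 = SyntheticSpec(grid_shape=(8, 8), n_domains=2, n_genes=60,
                              n_markers_per_domain=8, seed=9)
        other = generate_slice(spec2)
        stacked = stack_slices([small_slice, other])
        assert stacked.n_cells == small_slice.n_cells + other.n_cells
        assert stacked.n_genes == 60
        assert np.array_equal(stacked.batch, [0] * small_slice.n_cells + [1] * other.n_cells)

    def test_self_stack_duplicates_cells(self, small_slice):
        stacked = stack_slices([small_slice, small_slice])
        assert stacked.n_cells == 2 * small_slice.n_cells
        assert len(set(stacked.cell_ids)) == stacked.n_cells

    def test_gene_set_intersection(self):
        a = toy_slice(np.ones((3, 3)))
        b = SliceData(
            counts=np.ones((2, 3)),
            gene_ids=["g1", "g2", "extra"],
            cell_ids=["x0", "x1"],
            coords=np.zeros((2, 2)),
        )
        out = stack_slices([a, b])
        assert out.gene_ids == ["g1", "g2"]

    def test_values_preserved_exactly(self, small_slice):
        stacked = stack_slices([small_slice, small_slice])
        assert np.array_equal(stacked.dense()[: small_slice.n_cells], small_slice.dense())

    def test_disjoint_genes_raise(self):
        a = toy_slice(np.ones((2, 2)))
        b = SliceData(
            counts=np.ones((2, 2)),
            gene_ids=["other1", "other2"],
            cell_ids=["x0", "x1"],
            coords=np.zeros((2, 2)),
        )
        with pytest.raises(ValueError, match="share no genes"):
            stack_slices([a, b])
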