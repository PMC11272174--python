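import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import stdgcc
from stdgcc.data_io import (FeatureMatrix, RawDataset, filter_genes,
                            load_dataset, normalize_log_scale, preprocess,
                            save_dataset, select_hvgs)
from stdgcc.errors import (AlignmentError, EmptyResultError, ParameterError,
                           ValidationError)


def small_raw(n=4, g=10, seed=0, labels=False):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 6, size=(n, g))
    counts[:, 0] = 1  # keep at least one gene everywhere-expressed
    return RawDataset(
        counts=counts,
        coords=rng.uniform(0, 100, size=(n, 2)),
        gene_names=np.array([f"g{j}" for j in range(g)], dtype=object),
        labels=rng.integers(1, 3, size=n) if labels else None,
        barcodes=np.array([f"bc{i}" for i in range(n)], dtype=object))


class TestLoading:
    def test_mtx_dir_roundtrip(self, tmp_path):
        raw = small_raw(labels=True)
        save_dataset(raw, str(tmp_path))
        back = load_dataset(str(tmp_path), format="mtx-dir")
        assert back.n_spots == 4 and back.n_genes == 10
        np.testing.assert_array_equal(back.counts, raw.counts)
        np.testing.assert_allclose(back.coords, raw.coords)
        np.testing.assert_array_equal(back.labels, raw.labels)

    def test_missing_coordinate_barcode_is_alignment_error(self, tmp_path):
        raw = small_raw()
        save_dataset(raw, str(tmp_path))
        coords = pd.read_csv(tmp_path / "coords.csv").iloc[:-1]
        coords.to_csv(tmp_path / "coords.csv", index=False)
        with pytest.raises(AlignmentError, match="bc3"):
            load_dataset(str(tmp_path), format="mtx-dir")

    def test_dense_table_with_embedded_labels(self, tmp_path):
        raw = small_raw(labels=True)
        df = pd.DataFrame(raw.counts, index=list(raw.barcodes),
                          columns=list(raw.gene_names))
        df["x"], df["y"] = raw.coords[:, 0], raw.coords[:, 1]
        df["label"] = raw.labels
        path = tmp_path / "table.csv"
        df.to_csv(path)
        back = load_dataset(str(path), format="dense")
        assert back.labels is not None and len(back.labels) == 4
        np.testing.assert_array_equal(back.counts, raw.counts)

    def test_10x_h5(self, tmp_path):
        import h5py
        import scipy.sparse as sp
        raw = small_raw()
        X = sp.csc_matrix(raw.counts.T)  # genes x barcodes, CSC as 10x writes
        path = tmp_path / "filtered.h5"
        with h5py.File(path, "w") as f:
            grp = f.create_group("matrix")
            grp.create_dataset("data", data=X.data.astype("int32"))
            grp.create_dataset("indices", data=X.indices.astype("int64"))
            grp.create_dataset("indptr", data=X.indptr.astype("int64"))
            grp.create_dataset("shape", data=np.array(X.shape, dtype="int32"))
            grp.create_dataset("barcodes",
                               data=np.array(raw.barcodes, dtype="S"))
            feats = grp.create_group("features")
            names = np.array(raw.gene_names, dtype="S")
            feats.create_dataset("id", data=names)
            feats.create_dataset("name", data=names)
            feats.create_dataset("feature_type",
                                 data=np.array([b"Gene Expression"] * 10))
            feats.create_dataset("genome", data=np.array([b"syn"] * 10))
        pd.DataFrame({"barcode": raw.barcodes, "x": raw.coords[:, 0],
                      "y": raw.coords[:, 1]}).to_csv(
            tmp_path / "pos.csv", index=False)
        back = load_dataset(str(path), format="10x-h5",
                            coords_source=str(tmp_path / "pos.csv"))
        np.testing.assert_array_equal(back.counts, raw.counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            RawDataset(counts=np.array([[1, -1]]), coords=np.zeros((1, 2)),
                       gene_names=np.array(["a", "b"], dtype=object))


class TestFilterGenes:
    def test_boundary_at_min_spots(self):
        # a gene seen in exactly min_spots spots is retained
        counts = np.zeros((6, 2), dtype=int)
        counts[:5, 0] = 1
        counts[:4, 1] = 1
        raw = RawDataset(counts=counts, coords=np.zeros((6, 2)),
                         gene_names=np.array(["in5", "in4"], dtype=object))
        out = filter_genes(raw, min_spots=5)
        assert list(out.gene_names) == ["in5"]

    def test_all_zero_gene_removed(self):
        counts = np.array([[1, 0], [2, 0], [1, 0], [3, 0], [1, 0]])
        raw = RawDataset(counts=counts, coords=np.zeros((5, 2)),
                         gene_names=np.array(["a", "zero"], dtype=object))
        assert list(filter_genes(raw, 1).gene_names) == ["a"]

    def test_dense_matrix_identity_and_idempotence(self):
        raw = small_raw(n=6, g=5, seed=3)
        raw.counts[raw.counts == 0] = 1
        once = filter_genes(raw, min_spots=1)
        np.testing.assert_array_equal(once.counts, raw.counts)
        twice = filter_genes(filter_genes(raw, 5), 5)
        np.testing.assert_array_equal(twice.counts,
                                      filter_genes(raw, 5).counts)

    def test_everything_removed_raises(self):
        raw = small_raw(n=3, g=2)
        with pytest.raises(EmptyResultError):
            filter_genes(raw, min_spots=4)


class TestNormalizeLogScale:
    def test_hand_computed_2x2_chain(self):
        # libraries are equal so normalization is the identity; log1p then
        # per-gene standardization gives +-1 exactly
        raw = RawDataset(counts=np.array([[1, 3], [3, 1]]),
                         coords=np.zeros((2, 2)),
                         gene_names=np.array(["a", "b"], dtype=object))
        fm = normalize_log_scale(raw)
        np.testing.assert_allclose(fm.X, [[-1, 1], [1, -1]], atol=1e-12)

    def test_columns_standardized(self):
        raw = small_raw(n=30, g=8, seed=1)
        fm = normalize_log_scale(raw)
        live = fm.X.std(axis=0) > 0
        np.testing.assert_allclose(fm.X.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(fm.X[:, live].std(axis=0), 1, atol=1e-9)

    def test_constant_gene_maps_to_zero_column(self):
        # equal library sizes keep gene 0 constant through normalization
        counts = np.array([[2, 4], [2, 4], [2, 4]])
        raw = RawDataset(counts=counts, coords=np.zeros((3, 2)),
                         gene_names=np.array(["c", "d"], dtype=object))
        fm = normalize_log_scale(raw)
        np.testing.assert_array_equal(fm.X, 0.0)
        assert any("constant" in s for s in fm.preprocessing_log)

    def test_scaling_is_idempotent_tail_step(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        X = (X - X.mean(0)) / X.std(0)
        Y = (X - X.mean(0)) / X.std(0)
        np.testing.assert_allclose(X, Y, atol=1e-9)

    def test_zero_library_spot_flagged(self):
        counts = np.array([[0, 0], [1, 2]])
        raw = RawDataset(counts=counts, coords=np.zeros((2, 2)),
                         gene_names=np.array(["a", "b"], dtype=object))
        with pytest.raises(ValidationError):
            normalize_log_scale(raw)


class TestSelectHvgs:
    def test_ranking_by_variance(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(0, np.sqrt(v), 50) for v in (5, 1, 3)])
        fm = FeatureMatrix(X=X, gene_subset=np.array(list("abc"), dtype=object))
        out = select_hvgs(fm, t=2)
        assert set(out.gene_subset) == {"a", "c"}

    def test_t_equals_f_keeps_all(self):
        fm = FeatureMatrix(X=np.random.default_rng(1).normal(size=(10, 4)),
                           gene_subset=np.array(list("abcd"), dtype=object))
        out = select_hvgs(fm, t=4)
        assert set(out.gene_subset) == set("abcd")

    def test_t_too_large_raises(self):
        fm = FeatureMatrix(X=np.zeros((5, 3)),
                           gene_subset=np.array(list("abc"), dtype=object))
        with pytest.raises(ParameterError):
            select_hvgs(fm, t=4)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6)) * np.array([1, 5, 2, 8, 3, 1.5])
        names = np.array([f"g{j}" for j in range(6)], dtype=object)
        fm = FeatureMatrix(X=X, gene_subset=names)
        perm = rng.permutation(6)
        fmp = FeatureMatrix(X=X[:, perm], gene_subset=names[perm])
        assert (set(select_hvgs(fm, 3).gene_subset)
                == set(select_hvgs(fmp, 3).gene_subset))


@given(st.integers(0, 2**31 - 1))
def test_preprocessing_permutation_equivariance(seed):
    raw = small_raw(n=8, g=12, seed=seed % 100)
    raw.counts += 1  # avoid zero libraries / empty filter results
    rng = np.random.default_rng(seed)
    perm = rng.permutation(raw.n_spots)
    permuted = RawDataset(counts=raw.counts[perm], coords=raw.coords[perm],
                          gene_names=raw.gene_names)
    a = preprocess(raw, min_spots=1, hvg_t=5)
    b = preprocess(permuted, min_spots=1, hvg_t=5)
    np.testing.assert_allclose(a.X[perm], b.X, atol=1e-9)
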