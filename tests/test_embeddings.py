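"""Normalisations and dimension-reduction methods."""

import numpy as np
import pytest

from schptm_bench import (
    SvdParams,
    cpm_lognorm,
    embed_cpm_pca,
    embed_lsi_eigen,
    embed_lsi_whitened,
    jaccard_kpca,
    nmf_embed,
    reference_embed,
    svd_embed,
    tfidf,
)
from schptm_bench.embeddings import _centered_svd
from schptm_bench.scoring import ari, cluster_cells

from conftest import dense_to_cm


class TestCpmLognorm:
    def test_closed_form_on_uniform_row(self, cm_factory):
        cm = cm_factory([[1, 1]])
        out = cpm_lognorm(cm).toarray()
        assert np.allclose(out, np.log1p(5e5))

    def test_zero_columns_stay_zero(self, cm_factory):
        cm = cm_factory([[1, 0, 3], [2, 0, 1]])
        assert np.all(cpm_lognorm(cm).toarray()[:, 1] == 0)

    def test_depth_invariance_per_row(self, cm_factory):
        dense = np.array([[1, 2, 3], [4, 0, 1]])
        scaled = dense.copy()
        scaled[0] *= 7
        a = cpm_lognorm(cm_factory(dense)).toarray()
        b = cpm_lognorm(cm_factory(scaled)).toarray()
        assert np.allclose(a[0], b[0], atol=1e-10)

    def test_zero_coverage_row_is_an_error(self, cm_factory):
        with pytest.raises(ValueError, match="zero-coverage"):
            cpm_lognorm(cm_factory([[0, 0], [1, 2]]))


class TestTfidf:
    def test_closed_form_single_cell_single_region(self, cm_factory):
        out = tfidf(cm_factory([[5]])).toarray()
        assert np.allclose(out, np.log1p(1e4))

    def test_idf_is_one_for_ubiquitous_region(self, cm_factory):
        # region present in all 4 equal-depth cells: TF = 1/2, IDF = 1
        dense = np.array([[3, 3], [3, 3], [3, 3], [3, 3]])
        out = tfidf(cm_factory(dense)).toarray()
        assert np.allclose(out, np.log1p(1e4 * 0.5))

    def test_depth_invariance_under_global_doubling(self, cm_factory):
        rng = np.random.default_rng(0)
        dense = rng.integers(0, 5, size=(6, 8)) + (rng.random((6, 8)) < 0.3)
        dense[dense.sum(axis=1) == 0, 0] = 1
        a = tfidf(cm_factory(dense)).toarray()
        b = tfidf(cm_factory(dense * 2)).toarray()
        assert np.allclose(a, b, atol=1e-10)

    def test_empty_matrix_is_an_error(self, cm_factory):
        with pytest.raises(ValueError, match="empty"):
            tfidf(cm_factory(np.zeros((3, 3))))


class TestSvdEmbed:
    def test_exact_rank2_reconstruction(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.random(10), rng.random(6)) + np.outer(rng.random(10), rng.random(6))
        Xc = X - X.mean(axis=0)
        U, s, Vt = _centered_svd(X, 2)
        assert np.allclose(U @ np.diag(s) @ Vt, Xc, atol=1e-8)

    def test_whitened_components_have_unit_variance(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 12))
        emb = svd_embed(X, SvdParams(4, "whitened", drop_first=False))
        assert np.allclose(emb.coords.var(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_eigen_scores_match_dense_pca_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.random((20, 15))
        emb = svd_embed(X, SvdParams(5, "eigen", drop_first=False))
        # dense eigendecomposition of the covariance as the oracle
        Xc = X - X.mean(axis=0)
        vals, vecs = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
        vals = vals[::-1][:5]
        assert np.allclose(emb.coords.var(axis=0, ddof=0) * X.shape[0] / (X.shape[0] - 1),
                           vals, atol=1e-8)
        scores = Xc @ vecs[:, ::-1][:, :5]
        assert np.allclose(np.abs(emb.coords), np.abs(scores), atol=1e-8)

    def test_drop_first_removes_the_leading_component(self):
        rng = np.random.default_rng(4)
        X = rng.random((25, 10))
        full = svd_embed(X, SvdParams(4, "eigen", drop_first=False))
        dropped = svd_embed(X, SvdParams(3, "eigen", drop_first=True))
        assert np.allclose(np.abs(dropped.coords), np.abs(full.coords[:, 1:4]), atol=1e-8)

    def test_rank_deficiency_error_names_achievable_rank(self):
        X = np.outer(np.arange(8.0), np.ones(6))  # rank 1 (0 after centering)
        with pytest.raises(ValueError, match="rank"):
            svd_embed(X, SvdParams(4, "eigen", drop_first=False))


class TestPresets:
    def test_default_dimensions(self, small_dataset):
        cm = small_dataset.hptm_counts
        assert embed_cpm_pca(cm).n_dims == 10
        assert embed_lsi_eigen(cm).n_dims == 10
        assert embed_lsi_whitened(cm).n_dims == 50

    def test_row_count_matches_cells(self, small_dataset):
        cm = small_dataset.hptm_counts
        for emb in (embed_cpm_pca(cm), embed_lsi_eigen(cm), jaccard_kpca(cm),
                    nmf_embed(cm, seed=0)):
            assert emb.n_cells == cm.n_cells
            assert np.array_equal(emb.barcodes, cm.barcodes)

    def test_lsi_recovers_types_on_strong_signal(self, small_dataset):
        from schptm_bench import make_fixed_bins, merge_bins

        coarse = merge_bins(small_dataset.hptm_counts,
                            make_fixed_bins(small_dataset.config.layout, 200_000))
        emb = embed_lsi_eigen(coarse)
        labels = cluster_cells(emb, 3, "kmeans", seed=0)
        assert ari(small_dataset.labels, labels.to_numpy()) > 0.9


class TestJaccardKpca:
    def test_hand_computed_similarities_and_dense_oracle(self, cm_factory):
        dense = np.array([[1, 1, 0], [1, 0, 1], [0, 0, 1]])
        cm = cm_factory(dense)
        # raw Jaccard oracle
        J = np.array([[1.0, 1 / 3, 0.0], [1 / 3, 1.0, 1 / 2], [0.0, 1 / 2, 1.0]])
        rowm = J.mean(axis=1, keepdims=True)
        K = J - rowm - rowm.T + J.mean()
        vals, vecs = np.linalg.eigh(K)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        expected = vecs[:, :2] * np.sqrt(np.clip(vals[:2], 0, None))
        emb = jaccard_kpca(cm, dim=2, normalize_ove=False)
        assert np.allclose(np.abs(emb.coords), np.abs(expected), atol=1e-10)

    def test_identical_and_disjoint_cells(self, cm_factory):
        dense = np.array([[1, 2, 0, 0], [3, 1, 0, 0], [0, 0, 1, 1]])
        B = (dense > 0).astype(float)
        inter = B @ B.T
        union = B.sum(1)[:, None] + B.sum(1)[None, :] - inter
        J = inter / union
        assert J[0, 1] == 1.0  # identical binary support
        assert J[0, 2] == 0.0  # disjoint support

    def test_dim_beyond_positive_eigenvalues_is_an_error(self, cm_factory):
        dense = np.array([[1, 0], [1, 0], [0, 1]])
        with pytest.raises(ValueError, match="eigenvalue"):
            jaccard_kpca(cm_factory(dense), dim=2, normalize_ove=False)


class TestNmf:
    def test_rank1_recovery(self, cm_factory):
        u = np.array([1, 2, 3, 4, 5.0])
        v = np.array([2, 1, 4.0])
        X = np.rint(np.outer(u, v)).astype(int)
        cm = cm_factory(X)
        emb = nmf_embed(cm, dim=1, seed=0)
        rel_err = emb.params_used["frobenius_error"] / np.linalg.norm(X)
        assert rel_err < 1e-4

    def test_embedding_is_nonnegative(self, small_dataset):
        emb = nmf_embed(small_dataset.hptm_counts, dim=5, seed=0)
        assert emb.coords.min() >= 0

    def test_more_iterations_do_not_increase_loss(self, cm_factory):
        rng = np.random.default_rng(5)
        cm = cm_factory(rng.integers(0, 6, size=(20, 12)))
        short = nmf_embed(cm, dim=3, seed=0, max_iter=5)
        long = nmf_embed(cm, dim=3, seed=0, max_iter=200)
        assert long.params_used["frobenius_error"] <= short.params_used["frobenius_error"] + 1e-9


class TestReferenceEmbed:
    def test_output_dims_capped_by_rank(self):
        rng = np.random.default_rng(6)
        rna = rng.integers(1, 10, size=(20, 30))
        emb = reference_embed(rna, [f"c{i}" for i in range(20)], dim=50)
        assert emb.n_dims <= 19

    def test_permutation_equivariance(self, small_dataset):
        rna = small_dataset.rna_counts
        bcs = small_dataset.barcodes
        emb = reference_embed(rna, bcs)
        perm = np.random.default_rng(0).permutation(len(bcs))
        emb_p = reference_embed(rna[perm], bcs[perm])
        assert np.allclose(emb_p.coords, emb.coords[perm], atol=1e-6)

    def test_kmeans_recovers_types_from_rna(self, small_dataset):
        emb = reference_embed(small_dataset.rna_counts, small_dataset.barcodes)
        labels = cluster_cells(emb, 3, "kmeans", seed=0)
        assert ari(small_dataset.labels, labels.to_numpy()) > 0.95


def test_embeddings_equivariant_to_row_permutation(small_dataset):
    from schptm_bench import make_fixed_bins, merge_bins

    coarse = merge_bins(small_dataset.hptm_counts,
                        make_fixed_bins(small_dataset.config.layout, 500_000))
    perm = np.random.default_rng(1).permutation(coarse.n_cells)
    permuted = coarse.subset_cells(perm)
    for method in (embed_cpm_pca, embed_lsi_eigen, lambda m: jaccard_kpca(m, dim=5)):
        a = method(coarse)
        b = method(permuted)
        assert np.allclose(b.coords, a.coords[perm], atol=1e-6)
        assert np.array_equal(b.barcodes, a.barcodes[perm])
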