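import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from zfbrain.preprocess import (QCThresholds, cluster, find_markers,
                                normalize_log, pca, qc_filter, select_hvgs)
from zfbrain.syndata import CountDataset


def _dataset(counts, mito=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = np.array([f"g{i:03d}" for i in range(n_genes)], dtype=object)
    return CountDataset(
        counts=counts, gene_ids=gene_ids,
        mito_flags=np.zeros(n_genes, bool) if mito is None else mito,
        cell_ids=np.array([f"c{i}" for i in range(n_cells)], dtype=object),
        genotype=np.array(["wt"] * n_cells, dtype=object),
        replicate=np.array(["r0"] * n_cells, dtype=object))


class TestQCFilter:
    def _mixed_dataset(self):
        rng = np.random.default_rng(0)
        n_genes = 600
        mito = np.zeros(n_genes, bool)
        mito[:10] = True
        cols = []
        # cell 0: only 150 detected genes -> fails min_genes
        c = np.zeros(n_genes, int)
        c[10:160] = 5
        cols.append(c)
        # cell 1: healthy (about 500 genes, ~5000 UMIs, ~5% mito)
        c = rng.poisson(8, n_genes)
        c[:10] = rng.poisson(30, 10)
        cols.append(c)
        # cell 2: mito fraction exactly at the 12% bound -> retained
        c = np.zeros(n_genes, int)
        c[10:510] = 11          # 5500 non-mito
        c[:10] = 75             # 750 mito; 750/6250 = 0.12
        cols.append(c)
        # cell 3: 9000 UMIs -> fails max_umis
        c = np.zeros(n_genes, int)
        c[10:310] = 30
        cols.append(c)
        return _dataset(np.stack(cols, axis=1), mito)

    def test_bounds_and_inclusive_mito(self):
        d = self._mixed_dataset()
        kept, report = qc_filter(d)
        assert list(kept.cell_ids) == ["c1", "c2"]
        assert report.failed_criteria[0] == ["min_genes"]
        assert report.failed_criteria[3] == ["max_umis"]
        assert report.failed_criteria[2] == []  # 12% mito is inclusive

    def test_idempotent(self):
        d = self._mixed_dataset()
        once, _ = qc_filter(d)
        twice, _ = qc_filter(once)
        np.testing.assert_array_equal(once.counts, twice.counts)

    def test_all_removed_raises_with_counts(self):
        d = _dataset(np.ones((50, 3), int))  # 50 genes < min_genes
        with pytest.raises(ValueError, match="min_genes"):
            qc_filter(d)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            QCThresholds(min_genes=500, max_genes=100)


class TestNormalizeLog:
    def test_scale_factor_identity(self):
        # one cell totalling 10,000 with a gene at 10 -> log(1 + 10)
        counts = np.zeros((3, 1), int)
        counts[0, 0] = 10
        counts[1, 0] = 9990
        out = normalize_log(_dataset(counts))
        assert out[0, 0] == pytest.approx(np.log1p(10))
        assert out[2, 0] == 0.0  # all-zero gene stays zero

    def test_scale_invariance(self):
        base = np.array([[3, 6], [7, 14], [0, 0]])
        out = normalize_log(_dataset(base))
        np.testing.assert_allclose(out[:, 0], out[:, 1])

    def test_library_size_recovered(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3, (40, 5)) + 1
        out = normalize_log(_dataset(counts))
        np.testing.assert_allclose(np.expm1(out).sum(axis=0),
                                   1e4, rtol=1e-10)

    def test_zero_total_cell_raises(self):
        counts = np.zeros((5, 2), int)
        counts[0, 0] = 4
        with pytest.raises(ValueError, match="zero total"):
            normalize_log(_dataset(counts))


class TestSelectHVGs:
    def test_high_variance_gene_ranked_first(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(5, (50, 400))
        # same mean (5) but ~10x the variance: NB with size 0.556
        counts[7] = rng.negative_binomial(0.556, 0.556 / 5.556, 400)
        ids = np.array([f"g{i:03d}" for i in range(50)], dtype=object)
        top = select_hvgs(counts, ids, n=5)
        assert top[0] == "g007"

    def test_all_genes_when_n_equals_total(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4, (20, 100))
        ids = np.array([f"g{i:02d}" for i in range(20)], dtype=object)
        assert set(select_hvgs(counts, ids, n=20)) == set(ids)

    def test_tie_break_lexicographic(self):
        counts = np.tile(np.array([1, 0, 2, 5, 0, 3] * 5), (4, 1))
        ids = np.array(["zz", "aa", "mm", "bb"], dtype=object)
        out = select_hvgs(counts, ids, n=2)
        assert list(out) == ["aa", "bb"]

    def test_too_many_requested(self):
        with pytest.raises(ValueError):
            select_hvgs(np.ones((3, 5)), np.array(list("abc")), n=10)


class TestPCA:
    def test_rank_one_data(self):
        u = np.linspace(1, 2, 30)
        v = np.linspace(0, 5, 20)
        matrix = np.outer(u, v)
        ids = np.array([f"g{i}" for i in range(30)], dtype=object)
        emb = pca(matrix, ids, n_pcs=3, scale=False)
        total = emb.explained_variance.sum()
        assert emb.explained_variance[0] / total > 0.999

    def test_matches_eigendecomposition(self):
        """Loadings agree with a brute-force eigendecomposition of the
        covariance matrix to 1e-8 (up to the shared sign convention)."""
        rng = np.random.default_rng(4)
        matrix = rng.normal(2.0, 1.0, (10, 10))
        ids = np.array([f"g{i}" for i in range(10)], dtype=object)
        emb = pca(matrix, ids, n_pcs=5, scale=False)
        x = matrix.T - matrix.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(x, rowvar=False))
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order[:5]]
        for j in range(5):
            i = np.argmax(np.abs(evecs[:, j]))
            if evecs[i, j] < 0:
                evecs[:, j] *= -1
        np.testing.assert_allclose(emb.loadings, evecs, atol=1e-8)
        np.testing.assert_allclose(emb.explained_variance,
                                   np.sort(evals)[::-1][:5], atol=1e-8)

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(5)
        matrix = rng.normal(size=(40, 60))
        ids = np.array([f"g{i}" for i in range(40)], dtype=object)
        a = pca(matrix, ids, n_pcs=4)
        b = pca(matrix, ids, n_pcs=4)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for j in range(4):
            i = np.argmax(np.abs(a.loadings[:, j]))
            assert a.loadings[i, j] > 0

    def test_n_pcs_too_large(self):
        with pytest.raises(ValueError):
            pca(np.ones((5, 4)), np.array(list("abcde")), n_pcs=6)


class TestCluster:
    def test_separable_clusters_fully_recovered(self, separable_dataset,
                                                separable_embedding):
        lab = cluster(separable_embedding, resolution=1.0, seed=0)
        ari = adjusted_rand_score(separable_dataset.true_cluster, lab.labels)
        assert ari == 1.0

    def test_cluster_count_nondecreasing_in_resolution(
            self, separable_embedding):
        ks = [cluster(separable_embedding, resolution=r, seed=0).n_clusters
              for r in (0.4, 1.0, 1.8)]
        assert ks == sorted(ks)

    def test_homogeneous_blob_single_cluster(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=(300, 5))
        from zfbrain.preprocess import Embedding
        loadings = np.eye(10, 5)
        emb = Embedding(n_pcs=5, loadings=loadings, scores=scores,
                        explained_variance=np.ones(5),
                        gene_ids=np.array([f"g{i}" for i in range(10)]))
        lab = cluster(emb, resolution=0.1, seed=0)
        assert lab.n_clusters == 1

    def test_too_few_cells(self, separable_embedding):
        from zfbrain.preprocess import Embedding
        emb = Embedding(n_pcs=2, loadings=np.eye(4, 2),
                        scores=np.random.default_rng(0).normal(size=(5, 2)),
                        explained_variance=np.ones(2),
                        gene_ids=np.array(list("abcd")))
        with pytest.raises(ValueError):
            cluster(emb, k_graph=20)


class TestFindMarkers:
    def test_injected_markers_recovered(self, separable_dataset):
        d = separable_dataset
        norm = normalize_log(d)
        table = find_markers(norm, d.gene_ids, d.true_cluster)
        for k, mks in d.marker_genes.items():
            found = set(table.loc[table["cluster"] == k, "gene"])
            frac = len(found & set(mks)) / len(mks)
            assert frac >= 0.9
            assert (table.loc[table["cluster"] == k, "adjusted_p"]
                    < 0.05).all()

    def test_low_fold_change_excluded(self):
        rng = np.random.default_rng(7)
        norm = rng.normal(1.0, 0.05, (20, 200))
        norm[3, :100] += np.log2(1.4)  # ~0.5 log2 units, below 0.75
        labels = np.array([0] * 100 + [1] * 100)
        ids = np.array([f"g{i}" for i in range(20)], dtype=object)
        table = find_markers(norm, ids, labels)
        assert "g3" not in set(table["gene"])

    def test_bonferroni_arithmetic(self):
        # raw p of 1e-6 with 100 genes tested -> adjusted 1e-4
        assert min(1e-6 * 100, 1.0) == pytest.approx(1e-4)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            find_markers(np.ones((5, 10)), np.array(list("abcde")),
                         np.zeros(10, int))
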