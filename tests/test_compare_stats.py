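import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfbrain.compare_stats import (alteration_test, composition_ratio,
                                   composition_zscores, enrichment_chisq,
                                   global_de_filter, knn_graph,
                                   marker_persistence, pc_alignment,
                                   pc_null_by_split, proportion_test)
from zfbrain.compare_stats import NeighborGraph
from zfbrain.preprocess import find_markers, normalize_log, pca
from zfbrain.syndata import SynthConfig, dysregulate, generate_counts


class TestKnnGraph:
    def test_collinear_middle_cell(self):
        scores = np.array([[0.0], [1.0], [2.0]])
        g = knn_graph(scores, k=2)
        assert set(g.indices[1]) == {0, 2}

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(50, 4))
        g = knn_graph(scores, k=7)
        for i in range(50):
            d = np.linalg.norm(scores - scores[i], axis=1)
            order = sorted((dist, j) for j, dist in enumerate(d) if j != i)
            expected = [j for _, j in order[:7]]
            assert list(g.indices[i]) == expected

    def test_duplicate_coordinates_tie_to_lower_index(self):
        scores = np.zeros((6, 2))
        scores[4] = [5, 5]
        scores[5] = [6, 6]
        g = knn_graph(scores, k=3)
        assert list(g.indices[3]) == [0, 1, 2]

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            knn_graph(np.zeros((10, 2)), k=19)


class TestCompositionZscores:
    def test_worked_cosine_example(self):
        """A cell with 2 neighbors both of genotype A against an expected
        (0.5, 0.5) mix: distance = 1 - 1/sqrt(2)."""
        # 6 cells on a line so neighborhoods are unambiguous
        indices = np.array([[1, 2], [0, 2], [1, 3], [2, 4], [3, 5], [3, 4]])
        graph = NeighborGraph(k=2, indices=indices)
        genotypes = np.array(["A", "A", "A", "B", "B", "B"])
        res = composition_zscores(graph, genotypes, n_permutations=10, seed=0)
        # cell 0's neighbors (1, 2) are both A
        assert res.observed_distance[0] == pytest.approx(1 - 1 / np.sqrt(2))
        # cell 2's neighbors (1, 3) are one of each = global mix
        assert res.observed_distance[2] == pytest.approx(0.0, abs=1e-12)

    def test_single_genotype_rejected(self):
        graph = NeighborGraph(k=1, indices=np.array([[1], [0], [0]]))
        with pytest.raises(ValueError, match="degenerate"):
            composition_zscores(graph, np.array(["A", "A", "A"]))

    def test_mean_z_near_zero_under_label_permutation(self, null_dataset):
        """Shuffled labels are exchangeable with the null, so z-scores
        average to ~0."""
        d = null_dataset
        emb = pca(normalize_log(d), d.gene_ids, n_pcs=10)
        g = knn_graph(emb, k=19)
        rng = np.random.default_rng(1)
        shuffled = rng.permutation(d.genotype)
        res = composition_zscores(g, shuffled, n_permutations=200, seed=2)
        assert abs(np.nanmean(res.z)) < 0.1


class TestPCAlignment:
    def test_self_alignment_is_identity(self, separable_embedding):
        e = separable_embedding
        res = pc_alignment(e.loadings, e.gene_ids, e.loadings, e.gene_ids,
                           n_pcs=10)
        np.testing.assert_allclose(res.best_match, 1.0, atol=1e-12)

    def test_sign_flip_invariance(self, separable_embedding):
        e = separable_embedding
        flipped = e.loadings.copy()
        flipped[:, 3] *= -1
        a = pc_alignment(e.loadings, e.gene_ids, flipped, e.gene_ids, 10)
        b = pc_alignment(e.loadings, e.gene_ids, e.loadings, e.gene_ids, 10)
        np.testing.assert_allclose(a.best_match, b.best_match)

    def test_random_orthogonal_loadings_match_poorly(self):
        """Independent random orthonormal bases in a 1,000-gene space have
        best-match cosine < 0.2 for every PC."""
        ids = np.array([f"g{i}" for i in range(1000)], dtype=object)
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            qa, _ = np.linalg.qr(rng.normal(size=(1000, 10)))
            qb, _ = np.linalg.qr(rng.normal(size=(1000, 10)))
            res = pc_alignment(qa, ids, qb, ids, n_pcs=10)
            assert res.best_match.max() < 0.2

    def test_no_shared_genes_rejected(self):
        a = np.eye(4, 2)
        with pytest.raises(ValueError):
            pc_alignment(a, np.array(list("abcd")), a,
                         np.array(list("wxyz")), n_pcs=2)

    def test_null_split_shape(self):
        cfg = SynthConfig(n_genes=300, n_cells_per_genotype=200,
                          genotype_labels=("wt",), n_clusters=3, seed=4)
        d = generate_counts(cfg)
        null = pc_null_by_split(d, 0.5, n_repeats=3, n_pcs=6, seed=0)
        assert null.shape == (18,)
        assert np.all((null >= 0) & (null <= 1 + 1e-12))


@pytest.fixture(scope="module")
def injected():
    base = SynthConfig(n_genes=500, n_clusters=4,
                       n_cells_per_genotype=400, marker_log2fc=2.0,
                       seed=21)
    d0 = generate_counts(base)
    cfg = SynthConfig(n_genes=500, n_clusters=4,
                      n_cells_per_genotype=400, marker_log2fc=2.0,
                      effect=dysregulate(2, d0.marker_genes[2], 1.0,
                                         genotype="mutant"), seed=21)
    return generate_counts(cfg)


class TestAlterationTest:
    def test_injected_cluster_flagged(self, injected):
        d = injected
        norm = normalize_log(d)
        markers = find_markers(norm, d.gene_ids, d.true_cluster)
        res = alteration_test(norm, d.gene_ids, d.true_cluster, d.genotype,
                              markers)
        best = res.loc[res["bonferroni_p"].idxmin(), "cluster"]
        assert best == 2
        assert res.loc[res["cluster"] == 2, "bonferroni_p"].iloc[0] < 0.05

    def test_null_not_flagged(self, null_dataset):
        d = null_dataset
        norm = normalize_log(d)
        markers = find_markers(norm, d.gene_ids, d.true_cluster)
        res = alteration_test(norm, d.gene_ids, d.true_cluster, d.genotype,
                              markers)
        assert (res["bonferroni_p"] >= 0.05).all()
        assert np.allclose(res["median_all_gene_ratio"], 1.0, atol=0.1)

    def test_markers_equal_all_genes_gives_max_p(self, null_dataset):
        d = null_dataset
        norm = normalize_log(d)
        # a marker table containing every gene for every cluster
        markers = pd.DataFrame(
            [(c, g) for c in np.unique(d.true_cluster) for g in d.gene_ids],
            columns=["cluster", "gene"])
        res = alteration_test(norm, d.gene_ids, d.true_cluster, d.genotype,
                              markers)
        assert (res["raw_p"] == 1.0).all()


class TestGlobalDEFilter:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "adjusted_p",
                                           "pct_a", "pct_b"])

    def test_fold_change_highlight(self):
        out = global_de_filter(self._table([("a", 1.2, 0.01, 0.5, 0.5)]))
        assert out["highlighted"].iloc[0]

    def test_nonsignificant_excluded(self):
        out = global_de_filter(self._table([("a", 3.0, 0.2, 0.5, 0.5)]))
        assert len(out) == 0

    def test_pct_ratio_highlight(self):
        out = global_de_filter(self._table([("a", 0.3, 0.01, 0.5, 0.2)]))
        assert out["highlighted"].iloc[0]          # ratio 2.5 > 2

    def test_moderate_gene_kept_but_not_highlighted(self):
        out = global_de_filter(self._table([("a", 0.5, 0.01, 0.5, 0.4)]))
        assert len(out) == 1 and not out["highlighted"].iloc[0]

    def test_zero_denominator_flagged_and_highlighted(self):
        out = global_de_filter(self._table([("a", 0.2, 0.01, 0.3, 0.0)]))
        assert out["pct_ratio_undefined"].iloc[0]
        assert out["highlighted"].iloc[0]


class TestMarkerPersistence:
    def _matrix(self, frac_in, frac_out):
        n = 200
        matrix = np.zeros((1, 2 * n))
        matrix[0, :int(frac_in * n)] = 1.0
        matrix[0, n:n + int(frac_out * n)] = 1.0
        labels = np.array([0] * n + [1] * n)
        return matrix, np.array(["gene"], dtype=object), labels

    @pytest.mark.parametrize("frac_out,expected", [
        (0.01, "transient"),
        (0.30, "sustained"),
        (0.10, "sustained"),   # threshold is inclusive
    ])
    def test_classification(self, frac_out, expected):
        m, ids, labels = self._matrix(0.6, frac_out)
        assert marker_persistence(m, ids, labels, 0, "gene") == expected

    def test_missing_gene(self):
        m, ids, labels = self._matrix(0.6, 0.0)
        with pytest.raises(ValueError):
            marker_persistence(m, ids, labels, 0, "nope")


class TestProportionTest:
    def _labels(self, fracs_by_exp, n=100):
        labels, genos, exps = [], [], []
        for (geno, exp), frac in fracs_by_exp.items():
            k1 = int(round(frac * n))
            labels += [1] * k1 + [0] * (n - k1)
            genos += [geno] * n
            exps += [exp] * n
        return (np.array(labels), np.array(genos, dtype=object),
                np.array(exps, dtype=object))

    def test_exact_p_for_complete_separation_4v4(self):
        """4 vs 4 experiments with non-overlapping fractions: the exact
        two-sided rank-sum p is 2/C(8,4) = 0.02857, verified here by
        enumeration over rank configurations."""
        wt = {("sibling_wt", f"w{i}"): f for i, f in
              enumerate((0.30, 0.32, 0.34, 0.36))}
        mut = {("mutant", f"m{i}"): f for i, f in
               enumerate((0.10, 0.12, 0.14, 0.16))}
        labels, genos, exps = self._labels(wt | mut)
        res = proportion_test(labels, genos, exps)
        p = res.loc[res["cluster"] == 1, "raw_p"].iloc[0]
        # enumeration oracle: count rank-sum statistics as extreme as
        # complete separation
        stats_all = [sum(c) for c in
                     itertools.combinations(range(8), 4)]
        observed = sum(range(4))  # all WT ranks below all mutant ranks
        extreme = sum(s <= observed or s >= sum(range(4, 8))
                      for s in stats_all)
        assert p == pytest.approx(extreme / len(stats_all))
        assert p == pytest.approx(0.02857142857)

    def test_identical_fractions_give_maximal_p(self):
        d = {(g, f"{g}{i}"): 0.3 for g in ("sibling_wt", "mutant")
             for i in range(3)}
        labels, genos, exps = self._labels(d)
        res = proportion_test(labels, genos, exps)
        assert (res["raw_p"] == 1.0).all()

    def test_fractions_sum_to_one(self):
        from zfbrain.compare_stats import cluster_fractions
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 5, 600)
        genos = np.repeat(["sibling_wt", "mutant"], 300)
        exps = np.tile(np.repeat(["e1", "e2", "e3"], 100), 2)
        frac = cluster_fractions(labels, genos, exps)
        sums = frac.groupby(["genotype", "experiment"])["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_single_experiment_rejected(self):
        d = {("sibling_wt", "a"): 0.3, ("mutant", "b"): 0.3,
             ("mutant", "c"): 0.3}
        labels, genos, exps = self._labels(d)
        with pytest.raises(ValueError, match="experiment"):
            proportion_test(labels, genos, exps)


class TestWorkedExamples:
    @pytest.mark.parametrize("a,b,expected", [
        (82.6, 4.4, 19),
        (73.5, 7.9, 9),
        (50.0, 50.0, 1),
    ])
    def test_composition_ratio(self, a, b, expected):
        _, rounded = composition_ratio(a, b)
        assert rounded == expected

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            composition_ratio(10.0, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.1, 99.9), st.floats(0.1, 99.9))
    def test_ratio_reciprocal(self, a, b):
        ra, _ = composition_ratio(a, b)
        rb, _ = composition_ratio(b, a)
        assert ra * rb == pytest.approx(1.0)

    def test_chisq_uniform_table(self):
        stat, p = enrichment_chisq([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_chisq_row_swap_symmetry(self):
        t = np.array([[120, 30], [80, 70]])
        s1, _ = enrichment_chisq(t)
        s2, _ = enrichment_chisq(t[::-1])
        assert s1 == pytest.approx(s2)

    def test_chisq_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            enrichment_chisq([[0, 0], [5, 5]])

    def test_neuron_progenitor_enrichment(self):
        """Counts reconstructed from the published percentages of neurons
        vs progenitors/early precursors in the two genotypes give a
        chi-squared p far below 2.2e-16."""
        wt_total, mut_total = 18443, 17029
        table = [[round(0.826 * wt_total), round(0.044 * wt_total)],
                 [round(0.735 * mut_total), round(0.079 * mut_total)]]
        _, p = enrichment_chisq(table)
        assert p < 2.2e-16
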