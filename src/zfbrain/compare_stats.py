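"""Genotype-comparison statistics for clustered scRNA-seq data.

The tests here ask, in complementary ways, whether cells of different
genotypes occupy the same transcriptomic landscape:

* **neighborhood composition z-scores** — for every cell, compare the
  genotype mix of its k nearest neighbors against the global genotype mix
  (cosine distance), standardized against a label-shuffling permutation null;
* **PC alignment** — match principal-component loadings across independently
  processed datasets by absolute cosine similarity, with a null built from
  random splits of a single dataset;
* **cluster-alteration test** — per cluster, compare WT/mutant expression
  ratios of marker genes against those of all detected genes;
* **proportion tests** — compare experiment-level cluster fractions between
  genotypes with exact rank-sum tests;
* small worked-example utilities (global DE filter, marker persistence,
  composition ratios, chi-squared enrichment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .preprocess import Embedding, normalize_log, pca, select_hvgs
from .syndata import CountDataset

__all__ = [
    "NeighborGraph",
    "CompositionZResult",
    "PCAlignmentResult",
    "knn_graph",
    "composition_zscores",
    "pc_alignment",
    "pc_alignment_test",
    "pc_null_by_split",
    "alteration_test",
    "global_de_filter",
    "marker_persistence",
    "proportion_test",
    "composition_ratio",
    "enrichment_chisq",
    "rank_test",
]


# ---------------------------------------------------------------------------
# shared rank test

def rank_test(x: np.ndarray, y: np.ndarray, paired: bool = False) -> float:
    """Two-sided rank test p value.

    Default is the exact-when-possible Mann-Whitney rank-sum for two
    independent samples; ``paired=True`` switches to the Wilcoxon signed-rank
    test for matched samples of equal length.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal lengths")
        d = x - y
        if np.all(d == 0):
            return 1.0
        return float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)
    method = "exact" if (len(x) <= 25 and len(y) <= 25
                         and len(np.unique(np.r_[x, y])) == len(x) + len(y)) \
        else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


# ---------------------------------------------------------------------------
# neighborhood composition

@dataclass
class NeighborGraph:
    k: int
    indices: np.ndarray       # cells x k neighbor indices, self excluded
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        n = self.indices.shape[0]
        if self.indices.shape[1] != self.k:
            raise ValueError("each neighbor list must have exactly k entries")
        if np.any(self.indices == np.arange(n)[:, None]):
            raise ValueError("a cell cannot be its own neighbor")


@dataclass
class CompositionZResult:
    observed_distance: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray                 # NaN where null_sd == 0
    n_permutations: int
    seed: int
    genotype_labels: np.ndarray

    @property
    def tail_fraction(self) -> float:
        """Fraction of cells with |z| > 1.96 (valid z only)."""
        ok = np.isfinite(self.z)
        return float(np.mean(np.abs(self.z[ok]) > 1.96))


def knn_graph(embedding: Embedding | np.ndarray, k: int = 19) -> NeighborGraph:
    """Euclidean k nearest neighbors in PC-score space, self excluded.

    Distance ties are broken by cell index (lower index wins), making the
    graph deterministic on degenerate coordinates.
    """
    scores = embedding.scores if isinstance(embedding, Embedding) else embedding
    n = scores.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=min(n, k + 2)).fit(scores)
    dist, idx = nn.kneighbors(scores)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        # stable sort on (distance, index) after dropping self
        cand = [(dist[i, j], idx[i, j]) for j in range(idx.shape[1])
                if idx[i, j] != i]
        cand.sort()
        out[i] = [c[1] for c in cand[:k]]
    return NeighborGraph(k=k, indices=out)


def _cosine_distance_to_expected(comp: np.ndarray,
                                 expected: np.ndarray) -> np.ndarray:
    """1 - cosine similarity of each row of comp against expected."""
    num = comp @ expected
    den = np.linalg.norm(comp, axis=1) * np.linalg.norm(expected)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(den > 0, num / den, 0.0)
    return 1.0 - sim


def composition_zscores(graph: NeighborGraph, genotypes: np.ndarray,
                        n_permutations: int = 100,
                        seed: int = 0) -> CompositionZResult:
    """Permutation z-score of neighborhood genotype composition per cell.

    The observed statistic is the cosine distance between a cell's
    k-neighbor genotype composition and the global genotype composition.
    The null shuffles genotype labels over cells (graph fixed) and records
    per-cell mean and standard deviation of the distance over
    ``n_permutations`` shuffles.
    """
    genotypes = np.asarray(genotypes)
    labels, codes = np.unique(genotypes, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("degenerate labels: need >=2 genotypes")
    n, k = graph.indices.shape
    expected = np.bincount(codes, minlength=len(labels)) / n
    onehot = np.eye(len(labels))[codes]                       # n x G
    comp = onehot[graph.indices].sum(axis=1) / k              # n x G
    observed = _cosine_distance_to_expected(comp, expected)

    rng = np.random.default_rng(seed)
    acc = np.zeros(n)
    acc2 = np.zeros(n)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        comp_p = onehot[perm][graph.indices].sum(axis=1) / k
        d = _cosine_distance_to_expected(comp_p, expected)
        acc += d
        acc2 += d * d
    null_mean = acc / n_permutations
    null_var = np.maximum(acc2 / n_permutations - null_mean ** 2, 0.0)
    null_sd = np.sqrt(null_var)
    z = np.full(n, np.nan)
    ok = null_sd > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} cells have null_sd=0; z set to NaN")
    z[ok] = (observed[ok] - null_mean[ok]) / null_sd[ok]
    return CompositionZResult(observed_distance=observed, null_mean=null_mean,
                              null_sd=null_sd, z=z,
                              n_permutations=n_permutations, seed=seed,
                              genotype_labels=labels)


# ---------------------------------------------------------------------------
# PC alignment

@dataclass
class PCAlignmentResult:
    similarity: np.ndarray      # n_pcs x n_pcs signed cosine similarities
    best_match: np.ndarray      # per PC of A: max_j |similarity[i, j]|
    null_best_match: np.ndarray | None = None
    p_value: float | None = None


def pc_alignment(loadings_a: np.ndarray, gene_ids_a: np.ndarray,
                 loadings_b: np.ndarray, gene_ids_b: np.ndarray,
                 n_pcs: int = 15) -> PCAlignmentResult:
    """Cosine-similarity matching of PCs across two datasets.

    Both loading matrices are restricted to the shared gene set, then the
    full cosine-similarity matrix is computed and each PC of A is assigned
    its best absolute match among the PCs of B (PC sign is arbitrary).
    """
    ids_a = pd.Index(np.asarray(gene_ids_a, dtype=object))
    ids_b = pd.Index(np.asarray(gene_ids_b, dtype=object))
    shared = ids_a.intersection(ids_b)
    if len(shared) < 2:
        raise ValueError("need >=2 shared genes between loading matrices")
    if n_pcs > loadings_a.shape[1] or n_pcs > loadings_b.shape[1]:
        raise ValueError("n_pcs exceeds available loading columns")
    a = loadings_a[ids_a.get_indexer(shared), :n_pcs]
    b = loadings_b[ids_b.get_indexer(shared), :n_pcs]
    a = a / np.linalg.norm(a, axis=0)
    b = b / np.linalg.norm(b, axis=0)
    sim = a.T @ b
    best = np.max(np.abs(sim), axis=1)
    return PCAlignmentResult(similarity=sim, best_match=best)


def pc_null_by_split(dataset: CountDataset, split_ratio: float = 0.5,
                     n_repeats: int = 10, n_pcs: int = 15,
                     n_hvg: int | None = None,
                     seed: int = 0) -> np.ndarray:
    """Null distribution of PC best-match values from random splits.

    Repeatedly split one dataset's cells into two groups at ``split_ratio``,
    run the preprocessing PCA chain on each half independently, align the
    halves' PCs, and pool the per-PC best matches over repeats. Returns an
    array of length ``n_repeats * n_pcs``.
    """
    rng = np.random.default_rng(seed)
    n = dataset.n_cells
    n_a = int(round(split_ratio * n))
    if min(n_a, n - n_a) < n_pcs:
        raise ValueError("split half smaller than n_pcs")
    pooled = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        half_a = dataset.subset_cells(perm[:n_a])
        half_b = dataset.subset_cells(perm[n_a:])
        emb_a = _pca_chain(half_a, n_pcs, n_hvg)
        emb_b = _pca_chain(half_b, n_pcs, n_hvg)
        res = pc_alignment(emb_a.loadings, emb_a.gene_ids,
                           emb_b.loadings, emb_b.gene_ids, n_pcs=n_pcs)
        pooled.append(res.best_match)
    return np.concatenate(pooled)


def _pca_chain(dataset: CountDataset, n_pcs: int,
               n_hvg: int | None) -> Embedding:
    norm = normalize_log(dataset)
    hvg = None
    if n_hvg is not None:
        hvg = select_hvgs(dataset.counts, dataset.gene_ids, n=n_hvg)
    return pca(norm, dataset.gene_ids, hvg=hvg, n_pcs=n_pcs)


def pc_alignment_test(observed_best: np.ndarray,
                      null_best: np.ndarray) -> float:
    """Two-sided rank-sum p comparing observed vs null best-match values."""
    return rank_test(observed_best, null_best)


# ---------------------------------------------------------------------------
# cluster alteration

def alteration_test(matrix: np.ndarray, gene_ids: np.ndarray,
                    labels: np.ndarray, genotypes: np.ndarray,
                    markers: pd.DataFrame,
                    wt_label: str = "sibling_wt",
                    mutant_label: str = "mutant",
                    detected_min_frac: float = 0.05,
                    pseudocount: float = 1e-9) -> pd.DataFrame:
    """Per-cluster test for altered transcriptomes.

    For each cluster, compute the WT/mutant ratio of mean normalized
    expression for every gene detected in at least ``detected_min_frac`` of
    the cluster's cells, then compare the marker-gene ratio distribution
    against the all-detected-gene distribution with a two-sided rank test.
    p values are Bonferroni-corrected over clusters.
    """
    labels = np.asarray(labels)
    genotypes = np.asarray(genotypes)
    gene_ids = np.asarray(gene_ids, dtype=object)
    rows = []
    uniq = np.unique(labels)
    for c in uniq:
        in_c = labels == c
        wt = in_c & (genotypes == wt_label)
        mut = in_c & (genotypes == mutant_label)
        if wt.sum() == 0 or mut.sum() == 0:
            warnings.warn(f"cluster {c} lacks cells of both genotypes; "
                          "skipped")
            continue
        detected = (matrix[:, in_c] > 0).mean(axis=1) >= detected_min_frac
        if detected.sum() == 0:
            warnings.warn(f"cluster {c} has no detected genes; skipped")
            continue
        cluster_markers = markers.loc[markers["cluster"] == c, "gene"]
        marker_idx = np.isin(gene_ids, cluster_markers.to_numpy()) & detected
        if marker_idx.sum() == 0:
            warnings.warn(f"cluster {c} has no detected markers; skipped")
            continue
        mean_wt = matrix[:, wt].mean(axis=1)
        mean_mut = matrix[:, mut].mean(axis=1)
        ratio = (mean_wt + pseudocount) / (mean_mut + pseudocount)
        marker_ratios = ratio[marker_idx]
        all_ratios = ratio[detected]
        if marker_idx.sum() == detected.sum():
            p = 1.0  # identical distributions by construction
        else:
            p = rank_test(marker_ratios, all_ratios)
        rows.append((c, p, int(marker_idx.sum()), int(detected.sum()),
                     float(np.median(marker_ratios)),
                     float(np.median(all_ratios))))
    out = pd.DataFrame(rows, columns=["cluster", "raw_p", "n_markers",
                                      "n_detected_genes",
                                      "median_marker_ratio",
                                      "median_all_gene_ratio"])
    out["bonferroni_p"] = np.minimum(out["raw_p"] * len(out), 1.0)
    return out


# ---------------------------------------------------------------------------
# global DE filter

def global_de_filter(de_table: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Filter and highlight globally differentially expressed genes.

    Keeps rows with ``adjusted_p`` < alpha; highlights a kept gene when
    |log2fc| > 1 or the expressing-cell ratio across groups exceeds 2 or
    falls below 0.5. A zero denominator makes the ratio +inf (highlighted,
    flagged in ``pct_ratio_undefined``).
    """
    required = {"gene", "log2fc", "adjusted_p", "pct_a", "pct_b"}
    missing = required - set(de_table.columns)
    if missing:
        raise ValueError(f"de_table missing columns: {sorted(missing)}")
    kept = de_table[de_table["adjusted_p"] < alpha].copy()
    with np.errstate(divide="ignore"):
        ratio = np.where(kept["pct_b"] > 0,
                         kept["pct_a"] / kept["pct_b"], np.inf)
    kept["pct_ratio"] = ratio
    kept["pct_ratio_undefined"] = kept["pct_b"] == 0
    kept["highlighted"] = ((np.abs(kept["log2fc"]) > 1)
                           | (kept["pct_ratio"] > 2)
                           | (kept["pct_ratio"] < 0.5))
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# marker persistence

def marker_persistence(matrix: np.ndarray, gene_ids: np.ndarray,
                       labels: np.ndarray, precursor_cluster,
                       marker_gene: str,
                       outside_frac_threshold: float = 0.10) -> str:
    """Classify a precursor marker as transient or sustained.

    Sustained if the expressing fraction reaches ``outside_frac_threshold``
    (inclusive) in any cluster other than the precursor cluster; transient
    otherwise.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    gi = np.nonzero(gene_ids == marker_gene)[0]
    if len(gi) == 0:
        raise ValueError(f"gene {marker_gene!r} not found")
    labels = np.asarray(labels)
    if precursor_cluster not in labels:
        raise ValueError(f"cluster {precursor_cluster!r} not found")
    expressed = matrix[gi[0]] > 0
    for c in np.unique(labels):
        if c == precursor_cluster:
            continue
        if expressed[labels == c].mean() >= outside_frac_threshold:
            return "sustained"
    return "transient"


# ---------------------------------------------------------------------------
# proportions

def cluster_fractions(labels: np.ndarray, genotypes: np.ndarray,
                      experiments: np.ndarray) -> pd.DataFrame:
    """Per (cluster, genotype, experiment) fraction of the experiment's cells."""
    df = pd.DataFrame({"cluster": labels, "genotype": genotypes,
                       "experiment": experiments})
    counts = (df.groupby(["genotype", "experiment", "cluster"], sort=True)
                .size().rename("n").reset_index())
    totals = (df.groupby(["genotype", "experiment"], sort=True)
                .size().rename("total").reset_index())
    frac = counts.merge(totals, on=["genotype", "experiment"])
    frac["fraction"] = frac["n"] / frac["total"]
    # fill absent (cluster, experiment) combinations with fraction 0
    full = (frac.pivot_table(index=["genotype", "experiment"],
                             columns="cluster", values="fraction",
                             fill_value=0.0)
                .stack().rename("fraction").reset_index())
    return full


def proportion_test(labels: np.ndarray, genotypes: np.ndarray,
                    experiments: np.ndarray,
                    wt_label: str = "sibling_wt",
                    mutant_label: str = "mutant",
                    paired: bool = False) -> pd.DataFrame:
    """Rank test of experiment-level cluster fractions between genotypes.

    Every experiment contributes one fraction per cluster; per cluster the
    WT and mutant fraction samples are compared two-sided, with Bonferroni
    correction over clusters. Requires >=2 experiments per genotype.
    """
    frac = cluster_fractions(labels, genotypes, experiments)
    for g in (wt_label, mutant_label):
        n_exp = frac.loc[frac["genotype"] == g, "experiment"].nunique()
        if n_exp < 2:
            raise ValueError(f"genotype {g!r} has {n_exp} experiment(s); "
                             "test undefined")
    rows = []
    for c in sorted(frac["cluster"].unique()):
        sub = frac[frac["cluster"] == c]
        x = sub.loc[sub["genotype"] == wt_label, "fraction"].to_numpy()
        y = sub.loc[sub["genotype"] == mutant_label, "fraction"].to_numpy()
        rows.append((c, rank_test(x, y, paired=paired),
                     float(np.mean(x)), float(np.mean(y))))
    out = pd.DataFrame(rows, columns=["cluster", "raw_p", "mean_frac_wt",
                                      "mean_frac_mutant"])
    out["bonferroni_p"] = np.minimum(out["raw_p"] * len(out), 1.0)
    return out


# ---------------------------------------------------------------------------
# worked-example utilities

def composition_ratio(percent_class_a: float,
                      percent_class_b: float) -> tuple[float, int]:
    """Ratio of two percentage shares and its nearest-integer rendering."""
    if percent_class_b <= 0:
        raise ValueError("denominator percentage must be positive")
    r = percent_class_a / percent_class_b
    return r, int(round(r))


def enrichment_chisq(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 count table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)
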