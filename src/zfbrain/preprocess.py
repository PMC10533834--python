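"""Minimal scRNA-seq preprocessing core.

Implements the standard chain — cell QC, library-size log-normalization,
vst-style highly-variable-gene selection, PCA, kNN-graph Leiden clustering,
and one-vs-rest marker detection — with the defaults used throughout this
package's genotype comparisons: 200-4000 detected genes per cell, 400-8000
UMIs, <=12% mitochondrial reads, 2000 HVGs, rank-sum marker test with
positive-only log2FC >= 0.75 and Bonferroni-adjusted p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA
from sklearn.neighbors import NearestNeighbors

from .syndata import CountDataset

__all__ = [
    "QCThresholds",
    "QCReport",
    "Embedding",
    "ClusterLabels",
    "qc_filter",
    "normalize_log",
    "select_hvgs",
    "pca",
    "cluster",
    "find_markers",
]


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell quality-control bounds (all inclusive)."""

    min_genes: int = 200
    max_genes: int = 4000
    min_umis: int = 400
    max_umis: int = 8000
    max_mito_frac: float = 0.12

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes or self.min_umis >= self.max_umis:
            raise ValueError("min bound must be below max bound")
        if not 0 <= self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must be in [0, 1]")


@dataclass
class QCReport:
    """Pass/fail record for every input cell."""

    passed: np.ndarray                     # bool per cell
    failed_criteria: list[list[str]]       # per cell, names of failed checks

    def failure_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for crits in self.failed_criteria:
            for c in crits:
                out[c] = out.get(c, 0) + 1
        return out


@dataclass
class Embedding:
    """PCA loadings and cell scores."""

    n_pcs: int
    loadings: np.ndarray            # genes x n_pcs, unit-norm columns
    scores: np.ndarray              # cells x n_pcs
    explained_variance: np.ndarray  # non-increasing
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.loadings, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("loading columns must be unit norm")
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise ValueError("explained_variance must be non-increasing")


@dataclass
class ClusterLabels:
    labels: np.ndarray
    resolution: float
    k_graph: int
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def qc_filter(dataset: CountDataset,
              thresholds: QCThresholds = QCThresholds()
              ) -> tuple[CountDataset, QCReport]:
    """Filter cells on detected genes, total UMIs and mito fraction.

    All bounds are inclusive. Raises if no cell survives, reporting how many
    cells failed each criterion.
    """
    t = thresholds
    detected = (dataset.counts > 0).sum(axis=0)
    umis = dataset.counts.sum(axis=0)
    mito = dataset.counts[dataset.mito_flags].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umis > 0, mito / np.maximum(umis, 1), 1.0)

    failed: list[list[str]] = []
    for i in range(dataset.n_cells):
        crits = []
        if detected[i] < t.min_genes:
            crits.append("min_genes")
        if detected[i] > t.max_genes:
            crits.append("max_genes")
        if umis[i] < t.min_umis:
            crits.append("min_umis")
        if umis[i] > t.max_umis:
            crits.append("max_umis")
        if mito_frac[i] > t.max_mito_frac:
            crits.append("max_mito_frac")
        failed.append(crits)
    passed = np.array([len(c) == 0 for c in failed])
    report = QCReport(passed=passed, failed_criteria=failed)
    if not passed.any():
        raise ValueError(
            f"no cells pass QC; failure counts: {report.failure_counts()}")
    return dataset.subset_cells(passed), report


def normalize_log(dataset: CountDataset | np.ndarray,
                  scale_factor: float = 1e4) -> np.ndarray:
    """Library-size normalize each cell to ``scale_factor`` then log1p."""
    counts = dataset.counts if isinstance(dataset, CountDataset) else dataset
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("cell with zero total UMIs cannot be normalized")
    return np.log1p(counts * (scale_factor / totals))


def select_hvgs(counts: np.ndarray, gene_ids: np.ndarray,
                n: int = 2000) -> np.ndarray:
    """vst-style highly-variable genes.

    Ranks genes by the variance of their standardized counts, where each
    gene's counts are centered by its mean, scaled by an expected standard
    deviation from a mean-variance loess trend, and clipped at sqrt(n_cells).
    Ties break lexicographically on gene id.
    """
    n_genes, n_cells = counts.shape
    if n > n_genes:
        raise ValueError(f"requested {n} HVGs from {n_genes} genes")
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    # loess of log10(var) on log10(mean) over expressed genes, as in the
    # vst scheme; genes with zero variance keep expected sd 0 -> rank last
    not_const = var > 0
    est_var = np.zeros(n_genes)
    if not_const.sum() > 1:
        lx = np.log10(mean[not_const])
        ly = np.log10(var[not_const])
        # quadratic fit is a stable stand-in for span-0.3 loess at the gene
        # counts used here; the trend only sets per-gene expected sd
        coef = np.polyfit(lx, ly, deg=2)
        est_var[not_const] = 10 ** np.polyval(coef, lx)
    exp_sd = np.sqrt(est_var)
    clip = np.sqrt(n_cells)
    std_var = np.zeros(n_genes)
    for i in np.nonzero(exp_sd > 0)[0]:
        z = (counts[i] - mean[i]) / exp_sd[i]
        z = np.clip(z, -clip, clip)
        std_var[i] = z.var(ddof=1)
    order = sorted(range(n_genes), key=lambda i: (-std_var[i], str(gene_ids[i])))
    return np.asarray(gene_ids, dtype=object)[order[:n]]


def pca(matrix: np.ndarray, gene_ids: np.ndarray,
        hvg: np.ndarray | None = None, n_pcs: int = 15,
        scale: bool = True, max_value: float = 10.0) -> Embedding:
    """PCA of centered, optionally unit-variance-scaled expression.

    ``matrix`` is genes x cells log-normalized expression. The sign of every
    PC is fixed so its largest-magnitude loading entry is positive, making
    repeated runs bit-identical.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    if hvg is not None:
        sel = pd.Index(gene_ids).get_indexer(pd.Index(hvg))
        if np.any(sel < 0):
            raise ValueError("HVG not present in gene_ids")
        matrix = matrix[sel]
        gene_ids = gene_ids[sel]
    n_genes, n_cells = matrix.shape
    if n_pcs > min(n_genes, n_cells):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(genes, cells)")
    x = matrix.T.astype(float)                    # cells x genes
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = np.clip(x / sd, -max_value, max_value)
        x = x - x.mean(axis=0)
    model = _SkPCA(n_components=n_pcs, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T                # genes x n_pcs
    # sign convention: largest |loading| entry positive per PC
    for j in range(n_pcs):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return Embedding(n_pcs=n_pcs, loadings=loadings, scores=scores,
                     explained_variance=model.explained_variance_,
                     gene_ids=gene_ids)


def cluster(embedding: Embedding, resolution: float = 1.0,
            k_graph: int = 20, seed: int = 0) -> ClusterLabels:
    """Leiden community detection on a kNN graph of PC scores."""
    n_cells = embedding.scores.shape[0]
    if n_cells <= k_graph:
        raise ValueError(f"need more than k_graph={k_graph} cells")
    nn = NearestNeighbors(n_neighbors=k_graph + 1).fit(embedding.scores)
    _, idx = nn.kneighbors(embedding.scores)
    edges = {(min(i, j), max(i, j))
             for i in range(n_cells) for j in idx[i, 1:]}
    g = ig.Graph(n=n_cells, edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    return ClusterLabels(labels=np.asarray(part.membership, dtype=np.int64),
                         resolution=resolution, k_graph=k_graph, seed=seed)


def find_markers(matrix: np.ndarray, gene_ids: np.ndarray,
                 labels: np.ndarray, only_pos: bool = True,
                 logfc_threshold: float = 0.75, min_pct: float = 0.25,
                 alpha: float = 0.05, min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest rank-sum marker genes per cluster.

    For each cluster, every gene passing the fold-change and
    expressing-fraction prefilters is tested cluster-vs-rest with a two-sided
    Wilcoxon rank-sum on log-normalized expression; p values are
    Bonferroni-corrected over the number of genes in the matrix, and rows
    with adjusted p < alpha are kept.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters for marker detection")
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_genes = matrix.shape[0]
    expm1 = np.expm1(matrix)
    rows = []
    for c in uniq:
        in_c = labels == c
        if in_c.sum() < min_cells:
            warnings.warn(f"cluster {c} has <{min_cells} cells; skipped")
            continue
        out_c = ~in_c
        mean_in = expm1[:, in_c].mean(axis=1)
        mean_out = expm1[:, out_c].mean(axis=1)
        log2fc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)
        pct_in = (matrix[:, in_c] > 0).mean(axis=1)
        pct_out = (matrix[:, out_c] > 0).mean(axis=1)
        keep = np.maximum(pct_in, pct_out) >= min_pct
        if only_pos:
            keep &= log2fc >= logfc_threshold
        else:
            keep &= np.abs(log2fc) >= logfc_threshold
        for gi in np.nonzero(keep)[0]:
            stat, p = stats.ranksums(matrix[gi, in_c], matrix[gi, out_c])
            rows.append((c, gene_ids[gi], log2fc[gi], pct_in[gi],
                         pct_out[gi], p))
    table = pd.DataFrame(rows, columns=["cluster", "gene", "avg_log2fc",
                                        "pct_in", "pct_out", "raw_p"])
    table["adjusted_p"] = np.minimum(table["raw_p"] * n_genes, 1.0)
    table = table[table["adjusted_p"] < alpha].reset_index(drop=True)
    return table
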