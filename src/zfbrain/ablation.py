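"""In-silico cluster-ablation experiment and power analysis.

The experiment asks: if one genotype's cells of one cell type were missing,
would the standard analysis notice? One genotype's cells are removed from
one cluster, the truncated matrix is re-processed blind (no batch
correction), and a hypergeometric depletion test checks whether the ablated
cluster shows fewer cells of that genotype than its share of the surviving
pool predicts. Wrapping the experiment over cluster sizes and replicate
seeds yields a detection power curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import (ClusterLabels, Embedding, cluster, normalize_log,
                         pca, select_hvgs)
from .syndata import CountDataset, SynthConfig, ablate, generate_counts

__all__ = [
    "AblationResult",
    "PipelineConfig",
    "ablate_cluster",
    "reprocess_blind",
    "detect_missing_cluster",
    "run_ablation",
    "power_curve",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the blind re-processing chain."""

    n_hvg: int | None = None
    n_pcs: int = 14
    resolution: float = 1.0
    k_graph: int = 20
    seed: int = 0


@dataclass
class AblationResult:
    ablated_cluster: int | None
    table: pd.DataFrame      # per reference cluster: counts, depletion_p, rank
    detected: bool
    alpha: float


def ablate_cluster(dataset: CountDataset, cluster_label,
                   genotype: str,
                   reference_labels: np.ndarray | None = None
                   ) -> CountDataset:
    """Remove every cell of ``genotype`` in ``cluster_label``.

    ``reference_labels`` defaults to the dataset's ground-truth clusters.
    All other cells and all gene rows are untouched.
    """
    labels = (np.asarray(reference_labels) if reference_labels is not None
              else dataset.true_cluster)
    if labels is None:
        raise ValueError("no cluster labels available")
    target = (labels == cluster_label) & (dataset.genotype == genotype)
    if target.sum() == 0:
        raise ValueError(f"no cells with cluster={cluster_label!r}, "
                         f"genotype={genotype!r}")
    return dataset.subset_cells(~target)


def reprocess_blind(dataset: CountDataset,
                    config: PipelineConfig = PipelineConfig()
                    ) -> tuple[Embedding, ClusterLabels]:
    """Re-run normalize -> HVG -> PCA -> cluster from scratch.

    Deliberately applies no batch correction: correction can absorb exactly
    the genotype differences the ablation experiment is designed to expose.
    """
    norm = normalize_log(dataset)
    hvg = None
    if config.n_hvg is not None:
        hvg = select_hvgs(dataset.counts, dataset.gene_ids, n=config.n_hvg)
    emb = pca(norm, dataset.gene_ids, hvg=hvg, n_pcs=config.n_pcs)
    labels = cluster(emb, resolution=config.resolution,
                     k_graph=config.k_graph, seed=config.seed)
    return emb, labels


def detect_missing_cluster(embedding: Embedding, labels: ClusterLabels,
                           genotypes: np.ndarray,
                           reference_labels: np.ndarray,
                           mutant_label: str = "mutant",
                           ablated_cluster=None,
                           alpha: float = 0.05,
                           max_depletion_ratio: float = 0.5
                           ) -> AblationResult:
    """Hypergeometric depletion test per reference cluster.

    Reference labels are transferred to surviving cells by nearest
    reference-centroid in the re-computed PC space, where each reference
    centroid is the mean score of surviving cells carrying that reference
    label (ties broken by reference-id order). For each reference cluster
    the observed number of ``mutant_label`` cells among the cells assigned
    to it is compared with the expectation under the global genotype mix
    (hypergeometric lower tail). A cluster is "detected" as ablated when it
    ranks first by depletion p, passes Bonferroni over testable clusters,
    AND shows gross depletion (observed <= ``max_depletion_ratio`` x
    expected) — a missing cluster, in the sense visual inspection could
    flag, is substantially empty, not merely statistically short of cells.
    The blind cluster labels are carried in the result for inspection; the
    test itself depends only on the blind embedding.
    """
    genotypes = np.asarray(genotypes)
    reference_labels = np.asarray(reference_labels)
    scores = embedding.scores
    n = scores.shape[0]
    if not (len(genotypes) == len(reference_labels) == n):
        raise ValueError("label arrays must match embedding cells")

    ref_ids = np.unique(reference_labels)
    centroids = np.stack([scores[reference_labels == r].mean(axis=0)
                          for r in ref_ids])
    d2 = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assigned = ref_ids[np.argmin(d2, axis=1)]  # argmin takes first on ties

    total_mut = int((genotypes == mutant_label).sum())
    rows = []
    for r in ref_ids:
        in_r = assigned == r
        size = int(in_r.sum())
        obs = int((in_r & (genotypes == mutant_label)).sum())
        expected = size * total_mut / n
        if size == 0 or expected == 0:
            rows.append((r, expected, obs, size, np.nan, False))
            continue
        p = float(stats.hypergeom.cdf(obs, n, total_mut, size))
        rows.append((r, expected, obs, size, p, True))
    table = pd.DataFrame(rows, columns=["cluster", "n_expected_mutant",
                                        "n_observed_mutant", "n_assigned",
                                        "depletion_p", "testable"])
    n_testable = int(table["testable"].sum())
    # ranks: testable clusters by ascending p, ties by cluster id;
    # untestable clusters fill the remaining ranks
    order = table.sort_values(["testable", "depletion_p", "cluster"],
                              ascending=[False, True, True],
                              na_position="last").index
    ranks = pd.Series(np.arange(1, len(table) + 1), index=order)
    table["rank"] = ranks.sort_index().to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        table["depletion_ratio"] = (table["n_observed_mutant"]
                                    / table["n_expected_mutant"])

    def _passes(row) -> bool:
        return (int(row["rank"]) == 1
                and float(row["depletion_p"]) < alpha / n_testable
                and float(row["depletion_ratio"]) <= max_depletion_ratio)

    detected = False
    if ablated_cluster is not None and n_testable > 0:
        row = table[table["cluster"] == ablated_cluster]
        if len(row) == 1 and bool(row["testable"].iloc[0]):
            detected = _passes(row.iloc[0])
    else:
        # null screening mode: does ANY cluster pass the criterion?
        top = table[table["testable"]].nsmallest(1, "depletion_p")
        if len(top) and n_testable > 0:
            detected = _passes(top.iloc[0])
    if table[table["testable"] == False].shape[0]:  # noqa: E712
        warnings.warn("reference clusters without testable cells flagged")
    return AblationResult(ablated_cluster=ablated_cluster, table=table,
                          detected=bool(detected), alpha=alpha)


def run_ablation(dataset: CountDataset, cluster_label, genotype: str,
                 pipeline: PipelineConfig = PipelineConfig(),
                 alpha: float = 0.05) -> AblationResult:
    """Ablate -> reprocess blind -> detect, in one call."""
    truncated = ablate_cluster(dataset, cluster_label, genotype)
    emb, labels = reprocess_blind(truncated, pipeline)
    return detect_missing_cluster(emb, labels, truncated.genotype,
                                  truncated.true_cluster,
                                  mutant_label=genotype,
                                  ablated_cluster=cluster_label, alpha=alpha)


def power_curve(base_config: SynthConfig,
                cluster_fractions: list[float],
                n_replicates: int = 20,
                ablated_cluster: int = 0,
                genotype: str = "mutant",
                pipeline: PipelineConfig = PipelineConfig(),
                include_null: bool = True,
                alpha: float = 0.05,
                seed: int = 0) -> pd.DataFrame:
    """Detection rate of the ablation experiment across cluster sizes.

    For each target fraction, the ablated cluster's proportion is set to the
    fraction (remaining mass spread evenly over the other clusters) and the
    full simulate -> ablate -> reprocess -> detect chain is run
    ``n_replicates`` times. A fraction of 0 contributes a rate of 0 by
    construction. With ``include_null``, an un-ablated row measures the
    false-positive rate of the detector.
    """
    if len(cluster_fractions) == 0:
        raise ValueError("empty cluster-fraction grid")
    rng = np.random.default_rng(seed)
    rows = []
    for frac in cluster_fractions:
        if frac == 0:
            rows.append((frac, "ablated", 0.0, n_replicates))
            continue
        hits = 0
        for _ in range(n_replicates):
            props = np.full(base_config.n_clusters,
                            (1 - frac) / (base_config.n_clusters - 1))
            props[ablated_cluster] = frac
            cfg = dc_replace(base_config, cluster_proportions=props,
                             effect=ablate(ablated_cluster, genotype),
                             seed=int(rng.integers(0, 2**31 - 1)))
            data = generate_counts(cfg)
            emb, labels = reprocess_blind(data, pipeline)
            res = detect_missing_cluster(
                emb, labels, data.genotype, data.true_cluster,
                mutant_label=genotype, ablated_cluster=ablated_cluster,
                alpha=alpha)
            hits += int(res.detected)
        rows.append((frac, "ablated", hits / n_replicates, n_replicates))
    if include_null:
        fps = 0
        for _ in range(n_replicates):
            cfg = dc_replace(base_config, effect=None,
                             seed=int(rng.integers(0, 2**31 - 1)))
            data = generate_counts(cfg)
            emb, labels = reprocess_blind(data, pipeline)
            res = detect_missing_cluster(
                emb, labels, data.genotype, data.true_cluster,
                mutant_label=genotype, ablated_cluster=None, alpha=alpha)
            fps += int(res.detected)
        rows.append((np.nan, "null", fps / n_replicates, n_replicates))
    return pd.DataFrame(rows, columns=["cluster_fraction", "condition",
                                       "detection_rate", "n_replicates"])
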