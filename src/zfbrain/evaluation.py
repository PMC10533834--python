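"""Benchmark computations that quantify the pipeline's statistical behavior.

Each function simulates data under known conditions, runs the relevant
analysis stage from scratch, and returns the measured quantity:

* null calibration of the neighborhood permutation z-scores;
* power and false-positive rate of the in-silico ablation detector;
* agreement of the entropy thresholds with an exhaustive-search oracle;
* recovery of simulation parameters (marker effect size, cell-cycle phase
  fractions, cluster identity);
* self-consistency of the PC-alignment null and its sensitivity to an
  injected dysregulation;
* exact round-trip of saccade detection and the OKR counting rules.

The problem sizes used here are the package's benchmark defaults and are
documented in the methods note.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .ablation import PipelineConfig, power_curve
from .cellcycle import score_cell_cycle
from .compare_stats import (composition_zscores, knn_graph, pc_alignment,
                            pc_null_by_split, pc_alignment_test, _pca_chain)
from .hcr_quant import kapur_max_entropy_threshold, renyi_entropy_threshold
from .okr import detect_saccades, okr_index
from .preprocess import cluster, normalize_log, pca
from .syndata import (SynthConfig, cycle_continuum, dysregulate,
                      generate_counts, generate_eye_trace)

__all__ = [
    "neighborhood_null_calibration",
    "ablation_power_benchmark",
    "threshold_oracle_agreement",
    "parameter_recovery",
    "pc_alignment_consistency",
    "okr_roundtrip",
]


def neighborhood_null_calibration(n_seeds: int = 5,
                                  n_cells_per_genotype: int = 667,
                                  n_permutations: int = 100,
                                  k: int = 19, n_pcs: int = 14,
                                  seed: int = 0) -> dict:
    """Fraction of |z| > 1.96 on no-effect data (nominal rate 0.05).

    Simulates ~2,000 cells across the three genotype groups with no
    injected effect, embeds all cells jointly, and runs the neighborhood
    composition test; repeated over ``n_seeds`` independent simulations.
    Replicate mean-offsets are disabled here: the permutation null assumes
    exchangeable genotype labels, and replicate structure nested within
    genotype is a real (if tiny) label signal, not a calibration error.
    """
    rng = np.random.default_rng(seed)
    tails = []
    for _ in range(n_seeds):
        cfg = SynthConfig(n_cells_per_genotype=n_cells_per_genotype,
                          replicate_log2_sd=0.0,
                          seed=int(rng.integers(0, 2**31 - 1)))
        d = generate_counts(cfg)
        emb = pca(normalize_log(d), d.gene_ids, n_pcs=n_pcs)
        res = composition_zscores(knn_graph(emb, k=k), d.genotype,
                                  n_permutations=n_permutations,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        tails.append(res.tail_fraction)
    return {"mean_tail_fraction": float(np.mean(tails)),
            "per_seed": tails,
            "n_cells": 3 * n_cells_per_genotype}


def ablation_power_benchmark(cluster_fraction: float = 0.05,
                             n_replicates: int = 20,
                             marker_log2fc: float = 3.0,
                             n_cells_per_genotype: int = 700,
                             n_clusters: int = 5,
                             seed: int = 0) -> dict:
    """Detection power at a given ablated-cluster fraction plus the null
    false-positive rate of the detector.

    Replicate mean-offsets are disabled: they are nested within genotype,
    so they carry genuine genotype-linked structure and would contaminate
    the false-positive measurement, which requires cells exchangeable
    across genotypes.
    """
    base = SynthConfig(n_genes=500, n_cells_per_genotype=n_cells_per_genotype,
                       n_clusters=n_clusters, marker_log2fc=marker_log2fc,
                       n_markers_per_cluster=20, replicate_log2_sd=0.0,
                       seed=seed)
    report = power_curve(base, [cluster_fraction],
                         n_replicates=n_replicates,
                         pipeline=PipelineConfig(n_pcs=14),
                         include_null=True, seed=seed)
    power = float(report.loc[report["condition"] == "ablated",
                             "detection_rate"].iloc[0])
    fp = float(report.loc[report["condition"] == "null",
                          "detection_rate"].iloc[0])
    return {"power": power, "false_positive_rate": fp,
            "n_replicates": n_replicates}


def _oracle_entropy_threshold(hist: np.ndarray, alpha: float) -> int:
    """Exhaustive-search argmax of the two-class entropy objective.

    Deliberately naive (pure-python loops over all 256 candidate
    thresholds) so it is independent of the production implementation.
    """
    total = int(hist.sum())
    best_val, best_t = -math.inf, None
    for t in range(256):
        n0 = int(hist[: t + 1].sum())
        if n0 == 0 or n0 == total:
            continue
        p0 = n0 / total
        p1 = 1.0 - p0
        lo = [h / total / p0 for h in hist[: t + 1] if h > 0]
        hi = [h / total / p1 for h in hist[t + 1:] if h > 0]
        if alpha == 1:
            val = (-sum(x * math.log(x) for x in lo)
                   - sum(x * math.log(x) for x in hi))
        else:
            val = (math.log(sum(x ** alpha for x in lo)) / (1 - alpha)
                   + math.log(sum(x ** alpha for x in hi)) / (1 - alpha))
        if val > best_val:
            best_val, best_t = val, t
    return best_t


def threshold_oracle_agreement(n_histograms: int = 100,
                               seed: int = 0) -> dict:
    """Fraction of random histograms where Kapur and the per-alpha Renyi
    thresholds equal the exhaustive-search argmax (should be 1.0)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_histograms):
        h = rng.integers(0, 40, 256)
        peaks = rng.integers(0, 256, rng.integers(1, 6))
        h[peaks] += rng.integers(100, 2000, len(peaks))
        ok = kapur_max_entropy_threshold(h) == _oracle_entropy_threshold(h, 1)
        for alpha in (0.5, 2.0):
            ok &= (renyi_entropy_threshold(h, alphas=(alpha,))
                   == _oracle_entropy_threshold(h, alpha))
        agree += int(ok)
    return {"agreement": agree / n_histograms, "n": n_histograms}


def parameter_recovery(seed: int = 0) -> dict:
    """Recovery of injected simulation parameters.

    Measures (i) the worst per-cluster error of the empirical marker log2
    fold change against the configured value, (ii) the worst error of the
    recovered cell-cycle phase fractions in a cycling cluster against the
    configured mixture, and (iii) the adjusted Rand index of blind Leiden
    clustering against truth on well-separated clusters.
    """
    rng = np.random.default_rng(seed)
    # marker effect size
    cfg = SynthConfig(n_genes=400, n_cells_per_genotype=600, n_clusters=3,
                      marker_log2fc=2.0, replicate_log2_sd=0.0,
                      seed=int(rng.integers(0, 2**31 - 1)))
    d = generate_counts(cfg)
    fc_errors = []
    for k, mks in d.marker_genes.items():
        idx = np.isin(d.gene_ids, mks)
        in_c = d.true_cluster == k
        fc = np.log2(d.counts[idx][:, in_c].mean(axis=1)
                     / d.counts[idx][:, ~in_c].mean(axis=1))
        fc_errors.append(abs(float(np.median(fc)) - 2.0))
    # cell-cycle phase mixture
    cfg = SynthConfig(n_cells_per_genotype=667, n_clusters=3,
                      effect=cycle_continuum(0, (0.5, 0.25, 0.25)),
                      seed=int(rng.integers(0, 2**31 - 1)))
    d = generate_counts(cfg)
    cc = score_cell_cycle(normalize_log(d), d.gene_ids,
                          seed=int(rng.integers(0, 2**31 - 1)))
    in_c = d.true_cluster == 0
    phase_errors = []
    for ph, target in (("G1", None), ("S", None), ("G2M", None)):
        true_frac = float((d.true_phase[in_c] == ph).mean())
        rec_frac = float((cc.phase[in_c] == ph).mean())
        phase_errors.append(abs(rec_frac - true_frac))
    # cluster identity on separable data
    cfg = SynthConfig(n_genes=600, n_cells_per_genotype=300, n_clusters=3,
                      marker_log2fc=3.0, n_markers_per_cluster=20,
                      seed=int(rng.integers(0, 2**31 - 1)))
    d = generate_counts(cfg)
    emb = pca(normalize_log(d), d.gene_ids, n_pcs=14)
    labels = cluster(emb, resolution=1.0, seed=0)
    ari = float(adjusted_rand_score(d.true_cluster, labels.labels))
    return {"marker_log2fc_max_error": max(fc_errors),
            "phase_fraction_max_error": max(phase_errors),
            "cluster_ari": ari}


def _pc_fixture_kwargs() -> dict:
    """Study conditions for the PC-alignment experiments.

    Unequal cluster proportions keep the signal eigenvalues well separated
    (with near-degenerate eigenvalues the PC basis rotates freely inside
    the signal subspace and per-PC cosine matching is meaningless), and
    the number of compared PCs equals the number of signal dimensions
    (K - 1) so every compared PC is structure-bearing.
    """
    return dict(n_genes=400, n_clusters=4,
                cluster_proportions=np.array([0.4, 0.3, 0.2, 0.1]),
                marker_log2fc=3.0, n_markers_per_cluster=20)


def pc_alignment_consistency(n_seeds: int = 10, n_pcs: int = 3,
                             n_cells: int = 1200, seed: int = 0) -> dict:
    """Self-consistency of the random-split PC-alignment null, and its
    sensitivity to an injected cluster dysregulation.

    For each seed, two independent halves of one homogeneous-genotype
    dataset are aligned and compared against the pooled random-split null
    (rank-sum, two-sided); the halves come from the same population, so p
    should exceed 0.05 in nearly every seed. Separately, a 20-gene set is
    dysregulated x4 in one cluster of a second dataset, rotating that
    cluster's separation axis in gene space; at least one PC should then
    match the unperturbed dataset worse than the null's 5th percentile.
    The null is built from splits whose halves match the compared dataset
    sizes, as a fair null requires.
    """
    rng = np.random.default_rng(seed)
    kw = _pc_fixture_kwargs()
    consistent = 0
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31 - 1))
        d = generate_counts(SynthConfig(**kw, genotype_labels=("wt",),
                                        n_cells_per_genotype=2 * n_cells,
                                        seed=s))
        half_rng = np.random.default_rng(s + 1)
        perm = half_rng.permutation(d.n_cells)
        ha = d.subset_cells(perm[: d.n_cells // 2])
        hb = d.subset_cells(perm[d.n_cells // 2:])
        ea = _pca_chain(ha, n_pcs, None)
        eb = _pca_chain(hb, n_pcs, None)
        obs = pc_alignment(ea.loadings, ea.gene_ids, eb.loadings,
                           eb.gene_ids, n_pcs=n_pcs).best_match
        null = pc_null_by_split(d, 0.5, n_repeats=10, n_pcs=n_pcs,
                                seed=s + 2)
        consistent += int(pc_alignment_test(obs, null) > 0.05)

    # injected dysregulation: x4 on 20 background genes in cluster 0 of
    # dataset b only
    s = int(rng.integers(0, 2**31 - 1))
    da = generate_counts(SynthConfig(**kw, genotype_labels=("a",),
                                     n_cells_per_genotype=n_cells, seed=s))
    all_markers = set(sum(da.marker_genes.values(), []))
    background = [g for g in da.gene_ids
                  if g not in all_markers and not g.startswith("mt-")][:20]
    db = generate_counts(SynthConfig(**kw, genotype_labels=("b",),
                                     n_cells_per_genotype=n_cells,
                                     effect=dysregulate(0, background, 2.0,
                                                        genotype="b"),
                                     seed=s))
    d_null = generate_counts(SynthConfig(**kw, genotype_labels=("a",),
                                         n_cells_per_genotype=2 * n_cells,
                                         seed=s + 1))
    ea = _pca_chain(da, n_pcs, None)
    eb = _pca_chain(db, n_pcs, None)
    obs = pc_alignment(ea.loadings, ea.gene_ids, eb.loadings, eb.gene_ids,
                       n_pcs=n_pcs).best_match
    null = pc_null_by_split(d_null, 0.5, n_repeats=10, n_pcs=n_pcs,
                            seed=s + 3)
    below = bool(obs.min() < np.percentile(null, 5))
    return {"null_consistent_fraction": consistent / n_seeds,
            "dysregulation_below_null_q5": below,
            "n_seeds": n_seeds}


def okr_roundtrip(seed: int = 0) -> dict:
    """Exact recovery of scheduled saccades and the OKR counting rules.

    A trace with 5 left-eye and 3 right-eye scheduled saccades (one
    opposite-direction event per eye) is generated, detected, and scored;
    returns whether detection matched the schedule exactly and the
    resulting combined index (left 4 - 1 = 3, right 2 - 1 = 1, mean 2).
    """
    sched = [(3.0, "left", 1), (6.0, "left", 1), (9.0, "left", 1),
             (12.0, "left", -1), (15.0, "left", 1),
             (4.0, "right", 1), (8.0, "right", -1), (13.0, "right", 1)]
    trace = generate_eye_trace(duration=20.0, saccade_schedule=sched,
                               seed=seed)
    events = detect_saccades(trace)
    got = sorted((round(t), e, d) for t, e, d in events.events)
    want = sorted((int(t), e, d) for t, e, d in sched)
    idx = okr_index(events, expected_direction=1, window=(0.0, 20.0))
    return {"exact_recovery": float(got == want),
            "combined_index": idx.combined,
            "n_scheduled": len(sched)}
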