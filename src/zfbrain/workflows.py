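"""End-to-end orchestration of the genotype-comparison pipeline.

``run_genotype_comparison`` mirrors the study design: each genotype is
QC-filtered, normalized, embedded and clustered independently, markers are
called per genotype, and then the cross-genotype statistics run — the
neighborhood composition test on a joint embedding (the one analysis that
requires all genotypes in a shared space), PC alignment between genotype
pairs, the cluster-alteration and proportion tests, and cell-cycle phase
proportions. ``run_ablation_power`` composes the simulator with the
ablation detector into a power report. Every stage's seed is recorded in a
run manifest so reruns are byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .ablation import PipelineConfig, power_curve
from .cellcycle import phase_proportion_test, score_cell_cycle
from .compare_stats import (alteration_test, composition_zscores, knn_graph,
                            pc_alignment, proportion_test)
from .preprocess import (QCThresholds, cluster, find_markers, normalize_log,
                         pca, qc_filter, select_hvgs)
from .syndata import CountDataset, SynthConfig, generate_counts

__all__ = ["RunManifest", "ComparisonConfig", "run_genotype_comparison",
           "run_ablation_power"]


@dataclass
class RunManifest:
    config: dict[str, Any]
    seeds: dict[str, int] = field(default_factory=dict)
    version: str = __version__
    stages: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, seed: int | None = None) -> None:
        if seed is not None:
            self.seeds[stage] = int(seed)
        self.stages[stage] = "ok"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seeds": self.seeds,
             "version": self.version, "stages": self.stages},
            indent=2, default=str))


@dataclass
class ComparisonConfig:
    """Parameters of the full genotype comparison."""

    qc: QCThresholds = field(default_factory=QCThresholds)
    n_hvg: int | None = None
    n_pcs: int = 14
    resolution: float = 1.0
    k_graph: int = 20
    k_neighborhood: int = 19
    n_permutations: int = 100
    n_pcs_alignment: int = 14
    wt_label: str = "sibling_wt"
    mutant_label: str = "mutant"
    seed: int = 0


def _embed(dataset: CountDataset, cfg: ComparisonConfig):
    norm = normalize_log(dataset)
    hvg = None
    if cfg.n_hvg is not None:
        hvg = select_hvgs(dataset.counts, dataset.gene_ids, n=cfg.n_hvg)
    emb = pca(norm, dataset.gene_ids, hvg=hvg, n_pcs=cfg.n_pcs)
    return norm, emb


def run_genotype_comparison(dataset: CountDataset,
                            cfg: ComparisonConfig = ComparisonConfig(),
                            outdir: str | Path | None = None
                            ) -> dict[str, Any]:
    """Run all comparison statistics on one dataset of >=2 genotypes."""
    manifest = RunManifest(config=asdict(cfg))
    data, qc_report = qc_filter(dataset, cfg.qc)
    manifest.record("qc")

    genotypes = np.unique(data.genotype)
    per_genotype: dict[str, dict[str, Any]] = {}
    for g in genotypes:
        sub = data.subset_cells(data.genotype == g)
        norm, emb = _embed(sub, cfg)
        labels = cluster(emb, resolution=cfg.resolution,
                         k_graph=cfg.k_graph, seed=cfg.seed)
        markers = find_markers(norm, sub.gene_ids, labels.labels)
        per_genotype[str(g)] = {"dataset": sub, "norm": norm,
                                "embedding": emb, "labels": labels,
                                "markers": markers}
        manifest.record(f"preprocess[{g}]", seed=cfg.seed)

    # joint embedding for the neighborhood test
    norm_all, emb_all = _embed(data, cfg)
    graph = knn_graph(emb_all, k=cfg.k_neighborhood)
    composition = composition_zscores(graph, data.genotype,
                                      n_permutations=cfg.n_permutations,
                                      seed=cfg.seed)
    manifest.record("neighborhood", seed=cfg.seed)

    # PC alignment between every genotype pair
    alignment = {}
    for i, a in enumerate(genotypes):
        for b in genotypes[i + 1:]:
            ea = per_genotype[str(a)]["embedding"]
            eb = per_genotype[str(b)]["embedding"]
            alignment[f"{a}|{b}"] = pc_alignment(
                ea.loadings, ea.gene_ids, eb.loadings, eb.gene_ids,
                n_pcs=cfg.n_pcs_alignment)
    manifest.record("pc_alignment")

    # joint clustering backs the alteration / proportion / cycle stages
    labels_all = cluster(emb_all, resolution=cfg.resolution,
                         k_graph=cfg.k_graph, seed=cfg.seed)
    markers_all = find_markers(norm_all, data.gene_ids, labels_all.labels)
    alteration = alteration_test(norm_all, data.gene_ids, labels_all.labels,
                                 data.genotype, markers_all,
                                 wt_label=cfg.wt_label,
                                 mutant_label=cfg.mutant_label)
    manifest.record("alteration")
    proportions = proportion_test(labels_all.labels, data.genotype,
                                  data.replicate, wt_label=cfg.wt_label,
                                  mutant_label=cfg.mutant_label)
    manifest.record("proportions")

    # cell-cycle scoring requires the packaged gene sets to be present in
    # the matrix; datasets without them (e.g. plain synthetic gene ids)
    # skip the stage
    try:
        cc = score_cell_cycle(norm_all, data.gene_ids, seed=cfg.seed)
        phase_p = phase_proportion_test(cc.phase, data.genotype,
                                        data.replicate,
                                        wt_label=cfg.wt_label,
                                        mutant_label=cfg.mutant_label)
        manifest.record("cellcycle", seed=cfg.seed)
    except ValueError as err:
        cc = None
        phase_p = None
        manifest.stages["cellcycle"] = f"skipped: {err}"

    results = {"qc_report": qc_report, "per_genotype": per_genotype,
               "composition": composition, "pc_alignment": alignment,
               "alteration": alteration, "proportions": proportions,
               "cellcycle": cc, "phase_proportions": phase_p,
               "joint_labels": labels_all, "manifest": manifest}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        alteration.to_csv(outdir / "alteration.tsv", sep="\t", index=False)
        proportions.to_csv(outdir / "proportions.tsv", sep="\t", index=False)
        pd.DataFrame({"cell_id": data.cell_ids, "z": composition.z,
                      "observed_distance": composition.observed_distance}
                     ).to_csv(outdir / "composition_z.tsv", sep="\t",
                              index=False)
        manifest.write(outdir / "manifest.json")
    return results


def run_ablation_power(base_config: SynthConfig,
                       cluster_fractions: list[float],
                       n_replicates: int = 20,
                       pipeline: PipelineConfig = PipelineConfig(),
                       seed: int = 0,
                       outdir: str | Path | None = None) -> pd.DataFrame:
    """Simulate + ablate + detect over a grid of cluster sizes."""
    report = power_curve(base_config, cluster_fractions,
                         n_replicates=n_replicates, pipeline=pipeline,
                         seed=seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "ablation_power.tsv", sep="\t", index=False)
        RunManifest(config={"base_config": str(base_config),
                            "cluster_fractions": cluster_fractions,
                            "n_replicates": n_replicates},
                    seeds={"power": seed}).write(outdir / "manifest.json")
    return report
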