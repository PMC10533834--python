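"""Cell-cycle scoring with zebrafish S and G2M gene sets.

Scores follow the binned-control scheme: each set gene's expression is
compared against control genes sampled from the same mean-expression bin, so
a score measures set-specific elevation rather than overall transcriptional
activity. Phase is assigned from the two scores (G1 when neither is
positive), and phase proportions are compared between genotypes at the
experiment level with the same rank tests used for cluster proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .compare_stats import rank_test, cluster_fractions

__all__ = [
    "GeneSets",
    "CellCycleScores",
    "load_gene_sets",
    "score_gene_set",
    "assign_phase",
    "score_cell_cycle",
    "phase_proportion_test",
]


@dataclass(frozen=True)
class GeneSets:
    s_genes: tuple[str, ...]
    g2m_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.s_genes)) != len(self.s_genes) \
                or len(set(self.g2m_genes)) != len(self.g2m_genes):
            raise ValueError("gene sets must not contain duplicates")
        if set(self.s_genes) & set(self.g2m_genes):
            raise ValueError("S and G2M gene sets must be disjoint")


@dataclass
class CellCycleScores:
    s_score: np.ndarray
    g2m_score: np.ndarray
    phase: np.ndarray          # {G1, S, G2M} per cell
    n_bins: int
    n_ctrl: int
    seed: int


def load_gene_sets() -> GeneSets:
    """The packaged zebrafish S (50 genes) and G2M (52 genes) sets."""
    def read(name: str) -> tuple[str, ...]:
        text = (resources.files("zfbrain.data") / name).read_text()
        return tuple(line.strip() for line in text.splitlines() if line.strip())
    return GeneSets(s_genes=read("s_genes_zebrafish.txt"),
                    g2m_genes=read("g2m_genes_zebrafish.txt"))


def score_gene_set(matrix: np.ndarray, gene_ids: np.ndarray,
                   gene_set: tuple[str, ...] | list[str],
                   n_bins: int = 25, n_ctrl: int = 50,
                   seed: int = 0) -> np.ndarray:
    """Binned-control score of a gene set, one value per cell.

    Genes are binned into ``n_bins`` by mean expression over cells; for each
    set gene present in the matrix, ``n_ctrl`` control genes are sampled
    (uniformly, with replacement when the bin is small) from its bin,
    excluding all set genes. The score is the per-cell mean expression of
    the set minus the mean of the pooled controls.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    set_idx = np.nonzero(np.isin(gene_ids, np.asarray(gene_set, dtype=object)))[0]
    if len(set_idx) == 0:
        raise ValueError(f"no gene of the set is present in the matrix; "
                         f"missing: {sorted(gene_set)}")
    rng = np.random.default_rng(seed)
    # canonical gene order (by id) so scores do not depend on input order
    canon = np.argsort(gene_ids.astype(str), kind="stable")
    mean_expr = matrix.mean(axis=1)[canon]
    n_genes = len(gene_ids)
    order = np.argsort(mean_expr, kind="stable")   # ties break by gene id
    bin_of = np.empty(n_genes, dtype=np.int64)
    bin_of[order] = np.arange(n_genes) * n_bins // n_genes

    in_set = np.isin(gene_ids[canon], np.asarray(gene_set, dtype=object))
    ctrl_pos: list[int] = []
    for gi in np.nonzero(in_set)[0]:
        pool = np.nonzero((bin_of == bin_of[gi]) & ~in_set)[0]
        if len(pool) == 0:  # bin holds only set genes; widen to all non-set
            pool = np.nonzero(~in_set)[0]
        replace = len(pool) < n_ctrl
        ctrl_pos.extend(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl_idx = canon[np.asarray(sorted(set(ctrl_pos)), dtype=np.int64)]
    return matrix[set_idx].mean(axis=0) - matrix[ctrl_idx].mean(axis=0)


def assign_phase(s_score: np.ndarray, g2m_score: np.ndarray) -> np.ndarray:
    """Phase per cell: G1 unless a score is positive; ties with both
    positive go to S."""
    s_score = np.asarray(s_score, dtype=float)
    g2m_score = np.asarray(g2m_score, dtype=float)
    if not (np.all(np.isfinite(s_score)) and np.all(np.isfinite(g2m_score))):
        raise ValueError("scores must be finite")
    phase = np.full(s_score.shape, "G1", dtype=object)
    phase[(g2m_score > 0) & (g2m_score > s_score)] = "G2M"
    phase[(s_score > 0) & (s_score >= g2m_score)] = "S"
    return phase


def score_cell_cycle(matrix: np.ndarray, gene_ids: np.ndarray,
                     gene_sets: GeneSets | None = None,
                     n_bins: int = 25, n_ctrl: int = 50,
                     seed: int = 0) -> CellCycleScores:
    """S and G2M scores plus phase assignment for every cell."""
    sets = gene_sets if gene_sets is not None else load_gene_sets()
    s = score_gene_set(matrix, gene_ids, sets.s_genes, n_bins, n_ctrl, seed)
    g2m = score_gene_set(matrix, gene_ids, sets.g2m_genes, n_bins, n_ctrl,
                         seed + 1)
    return CellCycleScores(s_score=s, g2m_score=g2m,
                           phase=assign_phase(s, g2m),
                           n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)


def phase_proportion_test(phases: np.ndarray, genotypes: np.ndarray,
                          experiments: np.ndarray,
                          wt_label: str = "sibling_wt",
                          mutant_label: str = "mutant",
                          paired: bool = False) -> pd.DataFrame:
    """Per-phase rank test of experiment-level phase fractions.

    The per-experiment fraction of cells in each phase (G1/S/G2M) is
    compared between genotypes two-sided, one test per phase.
    """
    frac = cluster_fractions(np.asarray(phases), np.asarray(genotypes),
                             np.asarray(experiments))
    for g in (wt_label, mutant_label):
        n_exp = frac.loc[frac["genotype"] == g, "experiment"].nunique()
        if n_exp < 2:
            raise ValueError(f"genotype {g!r} has {n_exp} experiment(s); "
                             "test undefined")
    rows = []
    for ph in sorted(frac["cluster"].unique()):
        sub = frac[frac["cluster"] == ph]
        x = sub.loc[sub["genotype"] == wt_label, "fraction"].to_numpy()
        y = sub.loc[sub["genotype"] == mutant_label, "fraction"].to_numpy()
        rows.append((ph, rank_test(x, y, paired=paired),
                     float(np.mean(x)), float(np.mean(y))))
    return pd.DataFrame(rows, columns=["phase", "raw_p", "mean_frac_wt",
                                       "mean_frac_mutant"])
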