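"""Synthetic data generators emulating the study design.

Three kinds of fixtures are produced, matching the three data modalities the
analysis pipeline consumes:

* UMI count matrices with cluster structure, three genotypes and replicated
  experiments (negative-binomial noise model, cluster-specific marker genes);
* 3-D fluorescence stacks with Gaussian-blob signal, background noise and
  optional per-slice additive "spike" artifacts;
* eye-angle traces with smooth pursuit drift and step-like saccades.

Every generator records ground truth (cluster identity, cell-cycle phase,
signal mask, saccade schedule) so downstream statistics can be validated by
round-trip, and every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "SynthConfig",
    "CountDataset",
    "LabeledStack",
    "EyeTrace",
    "Effect",
    "ablate",
    "dysregulate",
    "proportion_shift",
    "cycle_continuum",
    "generate_counts",
    "generate_image_stack",
    "generate_eye_trace",
    "write_10x_triplet",
    "read_10x_triplet",
]

DEFAULT_GENOTYPES = ("unrelated_wt", "sibling_wt", "mutant")


# ---------------------------------------------------------------------------
# effect descriptors

@dataclass(frozen=True)
class Effect:
    """A genotype-specific perturbation injected into the simulation."""

    kind: str
    cluster: int | None = None
    genotype: str | None = None
    gene_set: tuple[str, ...] | None = None
    log2fc: float = 0.0
    factor: float = 1.0
    phase_fractions: tuple[float, float, float] = (1.0, 0.0, 0.0)


def ablate(cluster: int, genotype: str) -> Effect:
    """Remove every cell of ``genotype`` from ``cluster`` at generation time."""
    return Effect(kind="ablate", cluster=cluster, genotype=genotype)


def dysregulate(cluster: int, gene_set: Sequence[str], log2fc: float,
                genotype: str = "mutant") -> Effect:
    """Scale ``gene_set`` means by 2**log2fc in one cluster of one genotype."""
    return Effect(kind="dysregulate", cluster=cluster,
                  gene_set=tuple(gene_set), log2fc=log2fc, genotype=genotype)


def proportion_shift(cluster: int, genotype: str, factor: float) -> Effect:
    """Multiply one cluster's sampling probability by ``factor`` in a genotype."""
    return Effect(kind="proportion_shift", cluster=cluster, genotype=genotype,
                  factor=factor)


def cycle_continuum(cluster: int,
                    phase_fractions: tuple[float, float, float],
                    factor: float = 4.0) -> Effect:
    """Give one cluster a G1/S/G2M phase mixture.

    Cells drawn into ``cluster`` are assigned a phase with probabilities
    ``phase_fractions`` (G1, S, G2M); S cells have the packaged S gene set
    scaled by ``factor``, G2M cells the G2M set.
    """
    fr = np.asarray(phase_fractions, dtype=float)
    if fr.shape != (3,) or not np.isclose(fr.sum(), 1.0):
        raise ValueError("phase_fractions must be 3 values summing to 1")
    return Effect(kind="cycle_continuum", cluster=cluster,
                  phase_fractions=tuple(fr), factor=factor)


# ---------------------------------------------------------------------------
# configuration and containers

@dataclass
class SynthConfig:
    """Parameters of the count-matrix simulation.

    Defaults describe the study design this package targets: three genotype
    groups (unrelated WT, sibling WT, mutant) each sequenced in replicated
    experiments, with negative-binomial UMI noise and cluster-specific marker
    genes elevated over a flat baseline.
    """

    n_genes: int = 1000
    n_cells_per_genotype: int = 600
    genotype_labels: tuple[str, ...] = DEFAULT_GENOTYPES
    n_replicates_per_genotype: int = 2
    n_clusters: int = 5
    cluster_proportions: np.ndarray | None = None
    n_markers_per_cluster: int = 10
    marker_log2fc: float = 2.0
    baseline_mean: float = 1.0
    baseline_log_sd: float = 1.0
    dispersion: float = 2.0
    mito_gene_fraction: float = 0.02
    replicate_log2_sd: float = 0.05
    cycle_off_scale: float = 0.1
    effect: Effect | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_genotype <= 0:
            raise ValueError("n_genes and n_cells_per_genotype must be positive")
        if self.n_clusters <= 0:
            raise ValueError("n_clusters must be positive (K=0 is invalid)")
        if self.n_replicates_per_genotype <= 0:
            raise ValueError("n_replicates_per_genotype must be positive")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if not 0 <= self.mito_gene_fraction <= 1:
            raise ValueError("mito_gene_fraction must be in [0, 1]")
        if self.marker_log2fc < 0:
            raise ValueError("marker_log2fc must be >= 0")
        if self.cluster_proportions is None:
            self.cluster_proportions = np.full(self.n_clusters,
                                               1.0 / self.n_clusters)
        self.cluster_proportions = np.asarray(self.cluster_proportions,
                                              dtype=float)
        if self.cluster_proportions.shape != (self.n_clusters,):
            raise ValueError("cluster_proportions length must equal n_clusters")
        if abs(self.cluster_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")
        if self.effect is not None:
            self._validate_effect()

    def _validate_effect(self) -> None:
        eff = self.effect
        if eff.kind in ("ablate", "dysregulate", "proportion_shift",
                        "cycle_continuum"):
            if eff.cluster is not None and not (
                    0 <= eff.cluster < self.n_clusters):
                raise ValueError(f"effect cluster {eff.cluster} not in "
                                 f"[0, {self.n_clusters})")
            if eff.genotype is not None and \
                    eff.genotype not in self.genotype_labels:
                raise ValueError(f"effect genotype {eff.genotype!r} not one of "
                                 f"{self.genotype_labels}")
        else:
            raise ValueError(f"unknown effect kind {eff.kind!r}")


@dataclass
class CountDataset:
    """A genes x cells UMI matrix with per-cell metadata."""

    counts: np.ndarray               # genes x cells, non-negative int
    gene_ids: np.ndarray             # unique strings
    mito_flags: np.ndarray           # bool per gene
    cell_ids: np.ndarray             # unique strings
    genotype: np.ndarray             # label per cell
    replicate: np.ndarray            # label per cell
    true_cluster: np.ndarray | None = None
    true_phase: np.ndarray | None = None
    marker_genes: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.mito_flags) != n_genes:
            raise ValueError("gene metadata length mismatch")
        for name in ("cell_ids", "genotype", "replicate"):
            if len(getattr(self, name)) != n_cells:
                raise ValueError(f"{name} length != number of cells")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def subset_cells(self, keep: np.ndarray) -> "CountDataset":
        """Return a dataset restricted to the boolean/index cell selection."""
        return CountDataset(
            counts=self.counts[:, keep].copy(),
            gene_ids=self.gene_ids,
            mito_flags=self.mito_flags,
            cell_ids=self.cell_ids[keep],
            genotype=self.genotype[keep],
            replicate=self.replicate[keep],
            true_cluster=(None if self.true_cluster is None
                          else self.true_cluster[keep]),
            true_phase=(None if self.true_phase is None
                        else self.true_phase[keep]),
            marker_genes=dict(self.marker_genes),
        )


@dataclass
class LabeledStack:
    """A (z, y, x) intensity stack with ground-truth annotations."""

    intensities: np.ndarray
    true_signal_mask: np.ndarray
    region_masks: dict[str, np.ndarray]
    spike_slices_truth: set[int]

    def __post_init__(self) -> None:
        if self.intensities.shape != self.true_signal_mask.shape:
            raise ValueError("mask shape mismatch")
        for name, m in self.region_masks.items():
            if m.shape != self.intensities.shape:
                raise ValueError(f"region mask {name!r} shape mismatch")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class EyeTrace:
    """Left/right eye angle time series with a per-sample stimulation phase."""

    time: np.ndarray
    angle_left: np.ndarray
    angle_right: np.ndarray
    phase: np.ndarray                 # {stationary, moving, opto}
    expected_direction: int           # +1 or -1
    truth_saccades: list[tuple[float, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        n = len(self.time)
        if not (len(self.angle_left) == len(self.angle_right)
                == len(self.phase) == n):
            raise ValueError("trace arrays must share length")


# ---------------------------------------------------------------------------
# count-matrix generator

def _gene_means(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray,
                                           dict[int, list[str]],
                                           np.ndarray, np.ndarray]:
    """Per-cluster gene mean matrix (genes x K) plus gene metadata.

    Per-gene baselines are log-normal around ``baseline_mean`` (median), a
    realistic expression continuum; marker genes are drawn among
    well-expressed (above-median baseline) non-mito genes and elevated by
    ``marker_log2fc`` in their own cluster only.
    """
    rng = np.random.default_rng(cfg.seed)
    n_mito = int(round(cfg.mito_gene_fraction * cfg.n_genes))
    gene_ids = np.array(
        [f"mt-gene{i:04d}" if i < n_mito else f"gene{i:04d}"
         for i in range(cfg.n_genes)], dtype=object)
    mito_flags = np.char.startswith(gene_ids.astype(str), "mt-")

    base = cfg.baseline_mean * np.exp(
        rng.normal(0.0, cfg.baseline_log_sd, size=cfg.n_genes))
    means = np.tile(base[:, None], (1, cfg.n_clusters))
    markers: dict[int, list[str]] = {}
    # markers drawn from well-expressed non-mito genes, disjoint per cluster
    med = np.median(base)
    avail = [i for i in range(n_mito, cfg.n_genes) if base[i] >= med]
    need = cfg.n_markers_per_cluster * cfg.n_clusters
    if need > len(avail):
        raise ValueError("not enough well-expressed non-mito genes for "
                         "requested markers")
    chosen = rng.choice(avail, size=need, replace=False)
    for k in range(cfg.n_clusters):
        idx = chosen[k * cfg.n_markers_per_cluster:
                     (k + 1) * cfg.n_markers_per_cluster]
        means[idx, k] *= 2.0 ** cfg.marker_log2fc
        markers[k] = [str(gene_ids[i]) for i in sorted(idx)]
    return means, base, markers, gene_ids, mito_flags


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               size_param: float) -> np.ndarray:
    """NB draw parameterized by mean and size (inverse overdispersion)."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate_counts(cfg: SynthConfig) -> CountDataset:
    """Simulate a genes x cells UMI matrix under the configured study design.

    Counts are negative binomial with gene/cluster-specific means; replicates
    within a genotype receive a small log-normal mean offset so that
    experiment-level tests see realistic between-replicate variation. The
    configured effect, if any, perturbs a single (cluster, genotype) pair.
    """
    means, base, markers, gene_ids, mito_flags = _gene_means(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    eff = cfg.effect

    # packaged cell-cycle sets only materialize under cycle_continuum
    if eff is not None and eff.kind == "cycle_continuum":
        from .cellcycle import load_gene_sets
        sets = load_gene_sets()
        # graft real gene symbols onto the tail of the gene list so the
        # scorer sees the packaged sets
        cyc = list(sets.s_genes) + list(sets.g2m_genes)
        if len(cyc) > cfg.n_genes - cfg.n_markers_per_cluster * cfg.n_clusters:
            raise ValueError("n_genes too small for cycle_continuum fixture")
        tail = np.arange(cfg.n_genes - len(cyc), cfg.n_genes)
        replaced = set(gene_ids[tail])
        gene_ids = gene_ids.copy()
        gene_ids[tail] = cyc
        markers = {k: [g for g in v if g not in replaced]
                   for k, v in markers.items()}
        s_rows = tail[:len(sets.s_genes)]
        g2m_rows = tail[len(sets.s_genes):]
        # cycle genes are near-off outside their matching phase (replication
        # and mitosis machinery is silent in postmitotic cells)
        means[tail, :] = cfg.cycle_off_scale * base[tail, None]

    cols, genos, reps, clus, phases, ids = [], [], [], [], [], []
    for gi, g in enumerate(cfg.genotype_labels):
        props = cfg.cluster_proportions.copy()
        if (eff is not None and eff.kind == "proportion_shift"
                and eff.genotype == g):
            props[eff.cluster] *= eff.factor
            props /= props.sum()
        if eff is not None and eff.kind == "ablate" and eff.genotype == g:
            props[eff.cluster] = 0.0
            if props.sum() == 0:
                raise ValueError("ablation removes every cluster")
            props /= props.sum()
        cluster_of = rng.choice(cfg.n_clusters, size=cfg.n_cells_per_genotype,
                                p=props)
        rep_of = rng.integers(0, cfg.n_replicates_per_genotype,
                              size=cfg.n_cells_per_genotype)
        rep_offset = 2.0 ** rng.normal(0.0, cfg.replicate_log2_sd,
                                       size=(cfg.n_replicates_per_genotype,))
        for ci in range(cfg.n_cells_per_genotype):
            k = cluster_of[ci]
            mu = means[:, k] * rep_offset[rep_of[ci]]
            phase = "G1"
            if eff is not None and eff.kind == "cycle_continuum" \
                    and k == eff.cluster:
                phase = rng.choice(["G1", "S", "G2M"], p=eff.phase_fractions)
                mu = mu.copy()
                if phase == "S":
                    mu[s_rows] = eff.factor * base[s_rows] \
                        * rep_offset[rep_of[ci]]
                elif phase == "G2M":
                    mu[g2m_rows] = eff.factor * base[g2m_rows] \
                        * rep_offset[rep_of[ci]]
            if (eff is not None and eff.kind == "dysregulate"
                    and eff.genotype == g and k == eff.cluster):
                mu = mu.copy()
                sel = np.isin(gene_ids, eff.gene_set)
                mu[sel] *= 2.0 ** eff.log2fc
            cols.append(_nb_sample(rng, mu, cfg.dispersion))
            genos.append(g)
            reps.append(f"{g}_rep{rep_of[ci]}")
            clus.append(k)
            phases.append(phase)
            ids.append(f"cell_{gi}_{ci:05d}")

    counts = np.stack(cols, axis=1).astype(np.int64)
    return CountDataset(
        counts=counts,
        gene_ids=gene_ids,
        mito_flags=mito_flags,
        cell_ids=np.array(ids, dtype=object),
        genotype=np.array(genos, dtype=object),
        replicate=np.array(reps, dtype=object),
        true_cluster=np.array(clus, dtype=np.int64),
        true_phase=np.array(phases, dtype=object),
        marker_genes=markers,
    )


# ---------------------------------------------------------------------------
# image-stack generator

def generate_image_stack(shape: tuple[int, int, int] = (10, 96, 96),
                         n_blobs: int = 3,
                         signal_level: float = 180.0,
                         background_level: float = 20.0,
                         noise_sd: float = 5.0,
                         blob_radius: float = 16.0,
                         edge_width: float = 0.2,
                         z_aspect: float = 2.0,
                         spike_slices: set[int] | Sequence[int] = (),
                         spike_offset: float = 60.0,
                         n_regions: int = 2,
                         seed: int = 0) -> LabeledStack:
    """Simulate a confocal-like stack: plateau blobs over noisy background.

    Blobs are flat-topped (amplitude ``signal_level - background_level``)
    with a sigmoidal edge of width ``edge_width`` voxels, emulating compact
    labeled somata whose boundary is sharp relative to voxel size.
    Designated spike slices get a global additive offset, emulating the
    acquisition artifacts that break per-slice entropy thresholding and force
    the fallback path. The true signal mask (voxels whose noiseless signal
    exceeds half the blob amplitude) and the spike slice set are recorded.
    """
    if signal_level <= background_level:
        raise ValueError("signal level must exceed background level")
    nz, ny, nx = shape
    if min(shape) <= 0:
        raise ValueError("stack shape must be positive")
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    signal = np.zeros(shape)
    amp = signal_level - background_level
    # blob centers evenly spaced in z (so every slice carries signal),
    # random in-plane
    z_centers = np.linspace(1, nz - 1, max(n_blobs, 1))
    for b in range(n_blobs):
        cz = z_centers[b]
        cy = rng.uniform(blob_radius, ny - blob_radius)
        cx = rng.uniform(blob_radius, nx - blob_radius)
        d = np.sqrt(((zz - cz) * z_aspect) ** 2 + (yy - cy) ** 2
                    + (xx - cx) ** 2)
        # union of blobs (max, not sum): overlapping labels saturate
        signal = np.maximum(signal,
                            amp / (1.0 + np.exp((d - blob_radius)
                                                / edge_width)))
    true_mask = signal > amp / 2.0
    img = background_level + signal + rng.normal(0, noise_sd, size=shape)
    spike_set = set(int(z) for z in spike_slices)
    for z in spike_set:
        if not 0 <= z < nz:
            raise ValueError(f"spike slice {z} outside stack")
        img[z] += spike_offset
    # 8-bit detector range: offsets push bright voxels into saturation,
    # which is what makes spike slices break entropy thresholding
    img = np.clip(img, 0, 255)

    regions: dict[str, np.ndarray] = {}
    bounds = np.linspace(0, nx, n_regions + 1).astype(int)
    for r in range(n_regions):
        m = np.zeros(shape, dtype=bool)
        m[:, :, bounds[r]:bounds[r + 1]] = True
        regions[f"region{r}"] = m
    return LabeledStack(intensities=img, true_signal_mask=true_mask,
                        region_masks=regions, spike_slices_truth=spike_set)


# ---------------------------------------------------------------------------
# eye-trace generator

def generate_eye_trace(duration: float = 60.0,
                       fs: float = 100.0,
                       saccade_schedule: Sequence[tuple[float, str, int]] = (),
                       saccade_amplitude: float = 15.0,
                       pursuit_gain: float = 1.0,
                       noise_sd: float = 0.2,
                       expected_direction: int = 1,
                       refractory: float = 0.5,
                       opto_window: tuple[float, float] | None = None,
                       seed: int = 0) -> EyeTrace:
    """Simulate pursuit-plus-saccade eye-angle traces.

    The schedule lists (time, eye, direction) events; each adds a step of
    ``direction * saccade_amplitude`` degrees to that eye. A slow sinusoidal
    pursuit drift plus Gaussian noise forms the baseline. Two saccades of the
    same eye closer than ``refractory`` seconds are rejected.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    sched = sorted(saccade_schedule, key=lambda e: e[0])
    for ev in sched:
        if not 0 <= ev[0] < duration:
            raise ValueError(f"saccade at t={ev[0]} outside trace")
        if ev[1] not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")
    for eye in ("left", "right"):
        times = [ev[0] for ev in sched if ev[1] == eye]
        if any(b - a < refractory for a, b in zip(times, times[1:])):
            raise ValueError("overlapping saccades within refractory window")

    angles = {}
    for eye in ("left", "right"):
        base = pursuit_gain * 3.0 * np.sin(2 * np.pi * 0.1 * t)
        steps = np.zeros(n)
        for (st, ev_eye, direction) in sched:
            if ev_eye == eye:
                steps[t >= st] += direction * saccade_amplitude
        angles[eye] = base + steps + rng.normal(0, noise_sd, size=n)

    phase = np.full(n, "moving", dtype=object)
    if opto_window is not None:
        lo, hi = opto_window
        phase[(t >= lo) & (t < hi)] = "opto"
    return EyeTrace(time=t, angle_left=angles["left"],
                    angle_right=angles["right"], phase=phase,
                    expected_direction=expected_direction,
                    truth_saccades=list(sched))


# ---------------------------------------------------------------------------
# 10x-style triplet I/O

def write_10x_triplet(dataset: CountDataset, outdir: str | Path) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv + metadata.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx",
                 sparse.coo_matrix(dataset.counts), field="integer")
    pd.DataFrame({"gene_id": dataset.gene_ids}).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({"barcode": dataset.cell_ids}).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    meta = pd.DataFrame({
        "cell_id": dataset.cell_ids,
        "genotype": dataset.genotype,
        "replicate": dataset.replicate,
        "true_cluster": (dataset.true_cluster if dataset.true_cluster
                         is not None else ""),
        "true_phase": (dataset.true_phase if dataset.true_phase
                       is not None else ""),
    })
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)


def read_10x_triplet(indir: str | Path) -> CountDataset:
    """Load a dataset written by :func:`write_10x_triplet`."""
    indir = Path(indir)
    counts = np.asarray(spio.mmread(indir / "matrix.mtx").todense(),
                        dtype=np.int64)
    gene_ids = pd.read_csv(indir / "features.tsv", sep="\t",
                           header=None)[0].to_numpy(dtype=object)
    cell_ids = pd.read_csv(indir / "barcodes.tsv", sep="\t",
                           header=None)[0].to_numpy(dtype=object)
    meta = pd.read_csv(indir / "metadata.tsv", sep="\t")
    tc = meta["true_cluster"].to_numpy() if "true_cluster" in meta else None
    tp = (meta["true_phase"].to_numpy(dtype=object)
          if "true_phase" in meta else None)
    return CountDataset(
        counts=counts,
        gene_ids=gene_ids,
        mito_flags=np.char.startswith(gene_ids.astype(str), "mt-"),
        cell_ids=cell_ids,
        genotype=meta["genotype"].to_numpy(dtype=object),
        replicate=meta["replicate"].to_numpy(dtype=object),
        true_cluster=tc,
        true_phase=tp,
    )
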