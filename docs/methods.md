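# Methods

This note documents the models, parameter choices and numerical conventions
behind each module, what the synthetic data do and do not emulate, and the
limitations a user should keep in mind.

## Synthetic data

**Counts.** UMI counts are negative binomial, the standard overdispersed
noise model for droplet scRNA-seq: gene *g* in a cell of cluster *k* has
mean *μ(g, k)* and a common size (inverse-overdispersion) parameter
(default 2.0). Per-gene baselines are log-normal around `baseline_mean`
(median 1.0, log-sd 1.0), giving the mean-expression continuum that
rank-binned control matching (cell-cycle scoring) and vst-style HVG
selection both rely on; a flat baseline would make "expression-matched
control genes" an empty concept. Marker genes (default 10 per cluster,
disjoint across clusters, drawn from well-expressed non-mitochondrial
genes) are elevated by `marker_log2fc` in their own cluster only, so the
configured fold change is exactly the expected in/out log2 ratio and can be
checked by direct estimation. Replicates within a genotype receive a small
log-normal mean offset (default 0.05 log2 units) so experiment-level tests
see realistic between-replicate variation; it is set to 0 where an analysis
requires an exchangeable null (see *Calibration experiments*). Mitochondrial
genes are named with the zebrafish `mt-` prefix (default 2% of genes) so QC
can key on either names or flags.

Injected effects operate on a single (cluster, genotype) pair: `ablate`
removes the cells at generation time; `dysregulate` scales a gene set;
`proportion_shift` multiplies a cluster's sampling probability;
`cycle_continuum` assigns G1/S/G2M phases within one cluster and scales the
packaged S or G2M gene set (×4 by default) in matching-phase cells. Cycle
genes are near-off elsewhere (0.1 × their baseline): replication and
mitosis machinery is silent in postmitotic neurons, and that bimodality is
what makes binned-control scores reliably negative in non-cycling cells.

**Image stacks.** Confocal-like stacks are flat-topped ("plateau") blobs —
amplitude 160 over a background of 20, sigmoidal edge of width 0.2 voxels,
radius 16, z-extent compressed 2× — over Gaussian noise (sd 5), clipped to
the 8-bit range. Blob centers are evenly spaced in z so every slice carries
signal; the truth mask is the noiseless signal above half amplitude. The
sharp edge makes the ground truth essentially threshold-independent. Spike
slices receive a global additive offset; because the stack is 8-bit, the
offset drives the blob voxels into saturation, collapsing the signal class
of the histogram into a single bin — which is precisely the failure mode
that makes entropy thresholds dive into the background and produce a
binarized-pixel spike. (A pure offset without saturation is neutralized by
per-slice rescaling and provokes nothing.)

**Eye traces.** A slow sinusoidal pursuit component (0.1 Hz, gain-scaled
3° amplitude) plus scheduled step saccades (default 15°) and Gaussian
angle noise (sd 0.2°) at 100 Hz. Saccades of one eye closer than the
refractory period (0.5 s) are rejected at generation time.

What the generators do **not** emulate: gene–gene correlation beyond
cluster structure, doublets, ambient RNA, spatial autocorrelation of image
noise, registration error between region masks and stacks, and eye-tracking
segmentation artifacts. Passing tests therefore demonstrate correctness of
the statistics under their stated assumptions, not robustness to every
failure mode of real data.

## Preprocessing

QC bounds (200–4000 detected genes, 400–8000 UMIs, ≤12% mitochondrial
fraction) are all inclusive. Normalization scales each cell to 10,000
counts before log1p. HVG selection follows the vst scheme: a quadratic
trend of log10 variance on log10 mean (a stable stand-in for span-0.3 loess
at these gene counts) sets each gene's expected sd; standardized counts are
clipped at √n_cells; genes are ranked by the variance of the clipped
values, ties broken lexicographically by gene id. PCA operates on centered,
per-gene unit-variance-scaled (clipped at ±10) expression; each PC's sign
is fixed so its largest-magnitude loading is positive, making repeated runs
bit-identical. Clustering is Leiden (RB-configuration modularity) on an
undirected kNN graph (k = 20, Euclidean in PC space) with an exposed seed.
Markers are one-vs-rest rank-sum tests on log-normalized expression,
prefiltered at log2FC ≥ 0.75 (positive-only by default) and expressing
fraction ≥ 0.25, Bonferroni-corrected over the number of genes.

## Genotype-comparison statistics

**Neighborhood composition.** Neighborhoods are the k = 19 Euclidean
nearest neighbors in PC-score space (ties broken by cell index). The
observed statistic is 1 − cosine similarity between the neighborhood's
genotype-fraction vector (raw fractions, not centered) and the global
genotype fractions. The null shuffles genotype labels over cells (graph
fixed; default B = 100 shuffles) and records per-cell mean and sd; z =
(observed − mean)/sd, reported as missing where sd = 0. PC space is used
because it is the reproducible embedding the package controls; a 2-D layout
would add stochastic distortion without changing the question.

**PC alignment.** Loading matrices are restricted to shared genes,
re-normalized, and compared all-against-all by cosine similarity;
`best_match[i]` is the maximum *absolute* similarity (PC sign is
arbitrary). The null repeatedly splits one dataset and re-runs the full PCA
chain on each half. Two caveats govern experimental design here, both
verified empirically in this package's benchmarks: (i) per-PC cosine
matching is only meaningful when the signal eigenvalues are well separated
— with near-degenerate eigenvalues (e.g., equal-sized, equally distinct
clusters) the PC basis rotates freely inside the signal subspace and even
genuine replicates match poorly; (ii) the null split halves must match the
sizes of the datasets actually compared, otherwise the null is
systematically noisier than the observation. The benchmark fixture
therefore uses unequal cluster proportions (0.4/0.3/0.2/0.1), strong
markers, and compares K − 1 PCs.

**Cluster alteration.** Per cluster, the WT/mutant ratio of mean
normalized expression is computed for every gene detected in ≥5% of the
cluster's cells (pseudocount 1e-9 guards empty means); the marker-gene
ratio distribution is compared against the all-detected-gene distribution
with a two-sided Mann–Whitney rank-sum test (exact when sample sizes and
ties permit), Bonferroni-corrected over clusters. The named signed-rank
test is available via `rank_test(paired=True)` where a genuine pairing
exists, but marker-vs-all-genes and unpaired experiment groups are
structurally two-sample, so the rank-sum form is the default.

**Proportions.** Each experiment contributes one fraction per cluster
(fractions within an experiment sum to 1; absent combinations count 0).
Per cluster, the WT and mutant experiment-level fractions are compared
two-sided; with 4 vs 4 experiments, complete separation gives the exact
p = 2/C(8,4) = 0.02857. The same machinery drives the per-phase cell-cycle
comparison.

**Worked-example utilities.** `composition_ratio` returns the raw ratio and
its nearest-integer rendering. `enrichment_chisq` is the uncorrected
Pearson chi-squared on a 2×2 table — with counts in the thousands a
continuity correction is immaterial.

## Cell-cycle scoring

Binned-control scoring: genes are ranked by mean expression (rank-binned
into 25 equal-size bins, ties broken by gene id so results are independent
of gene order); each present set gene draws 50 control genes from its bin
(excluding all set genes; with replacement when a bin is small); the score
is the per-cell mean of the set minus the mean of the pooled controls.
Phase is G1 unless a score is positive; the larger positive score wins;
an exact positive tie goes to S. The packaged lists hold 50 S genes and 52
G2M genes (zebrafish symbols). Agreement with an independent implementation
of the same scheme (scanpy) is asserted at ≥90% phase concordance rather
than score equality, since control sampling is implementation-specific.

## In-silico ablation

The experiment removes one genotype's cells from one cluster and re-runs
the full chain — normalize, (optional) HVG, PCA, Leiden — from scratch
with no batch correction, since correction can absorb exactly the
difference being tested. Surviving cells are then assigned reference
identities per cell, by nearest reference-centroid in the blind PC space
(centroids are the mean blind-space scores of cells sharing a reference
label). Per reference cluster, the number of mutant cells among assigned
cells is tested for depletion against the global mutant fraction
(hypergeometric lower tail). Detection of the ablated cluster requires all
three of: rank 1 by depletion p, Bonferroni-corrected significance
(α = 0.05 over testable clusters), and gross depletion (observed ≤ 50% of
expected). The last criterion encodes what "a missing cluster" means: a
population visibly absent, not merely statistically short — and it is what
keeps the false-positive rate of the screen well below 5%, since a
Bonferroni test alone triggers at its nominal rate on true nulls.
Clusters with zero expected mutants are flagged untestable. The power
analysis re-simulates, re-processes and re-detects per replicate; the
benchmark condition is 5 clusters, 500 genes, 3×700 cells, strong markers
(log2FC 3, 20 markers per cluster), 20 replicates, with ablated-cluster
fraction 5%.

## HCR-FISH quantification

Each slice is min–max rescaled to 0–255 and thresholded on its own 256-bin
histogram. The Kapur maximum-entropy threshold maximizes the sum of the
two class entropies; the Rényi variant computes the maximizers for
α = 0.5, 1, 2 and combines the sorted thresholds with the Sahoo et al.
(1997) weighting rule (weights depend on whether the sorted thresholds lie
within 5 bins of each other). Class emptiness is decided on exact integer
masses, not float cumulative sums; ties take the lowest threshold; both
objectives are continuously verified against an exhaustive-search oracle.
Slices whose binarized-pixel count exceeds 3× the median of the ±2
neighboring slices are re-thresholded with the plain maximum-entropy rule
and recorded as spike slices. The mask times the intensity yields the
signal stack; per region, `signal_sum` is the intensity sum over binarized
voxels and `background_mean` the mean over in-region non-binarized voxels.
Two normalizations produce the heat matrices: per gene (row / row max) on
raw sums, and per region (column / column max) on background-normalized
values. Entropy thresholds inherently settle ~2 sd above the background
mode, so ~1% of background voxels are always masked; region sums are
intensity-weighted precisely so this faint scatter contributes little.

## OKR

Angular velocity is the first difference divided by the sampling step,
smoothed with a 5-sample boxcar (frame-to-frame tracking noise otherwise
produces spurious supra-threshold velocities); an event fires where
|velocity| first exceeds 100 °/s, with direction the sign at the crossing,
and further crossings of the same eye within 0.5 s suppressed. The OKR
index is, per eye, the count of in-window saccades in the expected
direction minus the opposite direction — a raw count difference, not
normalized per unit time — and the combined index is the mean of the two
eyes.

## Calibration experiments and problem sizes

The benchmark suite (`zfbrain.evaluation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses these
conditions, chosen once as the package's defaults: neighborhood
calibration at 3×667 cells, 1000 genes, B = 100, five simulations;
ablation power and false positives at 20 replicates each (condition
above); threshold-oracle agreement on 100 random histograms; parameter
recovery at 3×600 cells (markers), 3×667 cells (phases), 3×300 cells
(ARI); PC alignment over 10 seeds with 2400-cell datasets and
size-matched null splits. Calibration and false-positive runs disable the
replicate mean-offsets: those offsets are nested within genotype and are
therefore genuine genotype-linked structure, which an
exchangeability-based null is entitled to reject.

## Known limitations

- Batch correction (Harmony / anchor-based) is out of scope; corrected
  embeddings can be supplied externally wherever an `Embedding` is
  accepted.
- The neighborhood test's space (PC scores) is a documented convention;
  results in a nonlinear 2-D layout would differ.
- The ablation detector replaces the original visual UMAP inspection with
  a deterministic statistical surrogate; its absolute detection rates are
  not comparable to observer-dependent rates on real data.
- Cell-cycle scoring inherits the usual sensitivity of binned-control
  schemes to very sparse matrices (few expressed set genes per cell).
- The alteration and proportion tests assume at least two experiments per
  genotype and clusters populated by both genotypes; degenerate inputs are
  skipped with warnings rather than imputed.
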