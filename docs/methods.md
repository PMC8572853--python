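# Methods

## The pipeline in one paragraph

Raw UMI counts (genes x cells, two conditions) are QC-filtered per
condition, total-count log-normalized, reduced to 30 PCs over
variance-trend-selected HVGs, and Leiden-clustered at resolution 0.6.
Markers come from one-vs-rest Wilcoxon rank-sum tests with BH
adjustment. Program activity per cell is quantified by the binned
control Cell Score (CS). Dual-feature (non-professional phagocyte)
cells are called when a lineage score and the phagocytosis score both
exceed percentile thresholds, after Cd68+ extraction and doublet
exclusion. Cluster-level ligand-receptor interactions are scored as
products of cluster means with a label-permutation null. Every stage is
exercised against a synthetic generator with planted truth.

## Cell Score

Genes are ranked by mean log-normalized expression across all cells
(ties broken by gene id) and cut into `n_bins = 25` contiguous,
near-equal-size bins; when `n_genes mod n_bins = r`, the `r` lowest
bins take one extra gene. For each target gene in Gt,
`min(n_ctrl, available)` control genes (default `n_ctrl = 100`) are
drawn uniformly **without replacement** from the gene's bin,
**excluding all signature genes** (prevents self-matching inflation);
the pooled control multiset Gc concatenates the per-target draws, so a
gene drawn for two targets counts twice. Then per cell

    CS = mean over Gt of x − mean over Gc of x

on the log-normalized layer ("relative expression"). Controls are drawn
once per (signature, seed), not per cell; multi-signature scoring
derives a per-signature substream from `(seed, crc32(name))` so results
do not depend on the order of signatures in a list.

Interpretation choices that were genuinely open, and how they were
fixed: equal-size rank bins rather than equal-width expression
intervals (the convention of this scoring family); the log-normalized
layer without per-gene z-scoring; sampling without replacement and
signature-exclusion (neither is standard-defined). All are recorded in
output metadata and config-exposed.

**Null calibration.** The mean CS of a random signature on effect-free
data should be zero. Testing this needs a standard error that includes
the *gene-draw* variance: the across-cell SE (`sd/sqrt(n_cells)`)
shrinks with cell count while the target/control draw variability does
not, so it systematically over-rejects. The package therefore exposes
`per_target_differences` — across-cell means of (target − own
controls) per target gene — whose mean is the mean CS and whose spread
gives the appropriate SE. Measured over effect-free simulations this z
is close to standard normal (max |z| ≈ 2.9 over 20 seeds at 1,000
cells x 2,000 genes).

## QC and normalization

`n_features` counts genes with nonzero UMIs; `mito_fraction` is the
mitochondrial share of total UMIs (genes with the configurable,
case-insensitive `Mt-` prefix — the rat convention), defined as 0 for
an all-zero cell. Filters are strict inequalities, so boundary cells
(exactly 200/3000/4000 features, exactly the mito limit) are **kept** —
the literal reading of the stated thresholds, and config-exposed.
Removal reasons are reported with a fixed precedence (low features,
high features, high mito) so the per-reason counts partition the
removed set; precedence affects only the report, never the removed set.

Normalization is `ln(1 + scale · c / total)` with `scale = 10^4`
(the default of the toolkit the study used). HVG selection ranks genes
by variance divided by a lowess mean-variance trend (log-log scale);
PCA z-scores genes and clips z at ±10 to bound outlier leverage, and
fixes each component's sign by making its largest-magnitude loading
positive, so embeddings are fully deterministic.

## Markers

Per gene, cluster-vs-rest two-sided Wilcoxon rank-sum. Small tie-free
samples (n ≤ 25) use exact enumeration of the U null (the convention
of scipy's `auto` method and R's `wilcox.test`); otherwise a
tie-corrected normal approximation with continuity correction. The
plain normal approximation cannot reach the exact p within 0.02 at
n ≤ 10 (worst error 0.037 at 3 vs 3), which is why the exact path
exists. `log2FC = log2((m_in + 1)/(m_out + 1))` with `m` the mean of
`expm1(normalized)` — the pseudocount-1 convention of the study's
toolkit. BH adjustment is applied across genes **within** each cluster
(each cluster's marker list is its own family); the significance filter
is `p_adj < 0.05 AND |log2FC| > 2`, both strict.

## Dual-feature calls

Cd68+ means raw Cd68 count ≥ 1 (no threshold is standard; it is
config-exposed). The doublet heuristic flags cells whose `n_features`
strictly exceeds `median + 3·MAD` (raw MAD) within their condition;
with MAD = 0 only cells strictly above the median can ever be flagged.
A cell is dual-feature when its lineage score and phagocytosis score
both strictly exceed their thresholds, which default to the
within-dataset 75th percentiles — an explicit, tunable rule standing in
for the study's visual cluster-plus-scatter identification. On
full-dataset simulations at default settings this recovers planted
dual cells with sensitivity ~1.0 and specificity ~0.97; inside a Cd68+
subset, where phagocytes dominate, the percentile thresholds are
harsher and sensitivity drops for the rarer lineages — a property of
percentile thresholding in a skewed population, visible in
`analysis/03_scores_dual.py`.

## Ligand-receptor screen

For each annotated pair and ordered (sender, receiver) cluster pair —
including sender = receiver — the score is
`mean_ligand(sender) x mean_receptor(receiver)` on the normalized
layer. A record is valid only when both means reach 0.2 (the study's
stated validity cutoff, interpreted as cluster-mean normalized
expression and config-exposed). The null shuffles cluster labels over
cells globally and recomputes scores; `p = (1 + #{perm ≥ obs}) /
(n_perm + 1)` (never zero, bounded below by `1/(n_perm+1)`), BH
adjusted across valid records. The product score is a deliberate
simplification of full communication-probability models; the
permutation null and the 0.2 cutoff are the implementable stated
elements. Per-condition analyses run the screen on each condition's
cells separately.

## Synthetic generator

Counts are gamma-Poisson: gene g in cell c has mean
`libsize_c · w_g · mult_gc / Σ_g w_g mult_gc` with gene weights
`w ~ LogNormal(0,1)`, library sizes `LogNormal(ln 2500, 0.25)`, and a
shared dispersion of 5; `mult` elevates a cell's program genes by
`2^effect` (default effect 4, i.e. 16x). Because profiles are
renormalized per cell, expected totals are independent of cell type —
composition effects are never confounded with depth. The default
configuration plants 8 cell types in study-shaped proportions (normal:
epithelial 0.36 + fibroblast 0.32 ≈ two-thirds; inflamed: neutrophil
0.35 + macrophage 0.25), a 40-gene phagocytosis program carried by
macrophages and dendritic cells (Cd68, Cd14, ...), M1/M2 polarization
programs (M2 planted in macrophages, M1 in no one), proliferation and
osteoblastic programs, and 10 mitochondrial genes tuned to a 5% count
share. Named genes (Csf1/Csf1r, Il34, Ccl3/Ccr5, Cxcl1/Cxcr2,
Il1b/Il1r2, Igf1/Igf1r, Epcam, Mki67, Mrc1, ...) sit at the head of
their programs so signature files and the shipped ligand-receptor
table apply verbatim.

Dual-feature cells (5% of their host type, floor-rounded per
condition) multiplicatively elevate **both** their lineage program and
the phagocytosis program — genuinely co-expressing cells, not
mixtures: an Mki67+ progenitor population and an epithelial-phagocyte
population inside the epithelial type, and an osteoblastic-stromal
population inside fibroblasts. Doublets (5%) sum two random singlet
parents and thin the result binomially to 2.0x a fresh library-size
draw; realized doublet libraries come out ~1.7x a singlet's, matching
empirical droplet doublet UMI ratios (1.5–2x), which is what gives the
feature-count heuristic its signal.

What the generator does **not** emulate: batch effects between
replicate samples, ambient RNA, gene-gene correlation beyond programs,
zero-inflation beyond the NB law, or realistic transcriptome size
(2,000 genes, so the absolute feature-count filters rarely bind).
Passing tests therefore demonstrate correctness of the statistics and
recoverability of planted structure under a clean NB world — not
robustness to the full messiness of real tissue data.

## Problem sizes and determinism

Default experiment sizes are desk-scale by design: 1,000 cells per
condition and 2,000 genes for calibration and recovery benchmarks, 10
simulation seeds for the end-to-end dual-feature benchmark, 200–1,000
permutations for the screen. One global seed drives everything; stages
and signatures derive substreams by hashing their names, so adding a
stage never perturbs earlier draws, and two runs with the same config
and seed are byte-identical (verified file-by-file in the tests).

## Known limitations

- The exact dual-feature criterion of the original study is visual; the
  percentile rule here is an explicit stand-in, and its operating point
  depends on the population it is applied to (see above).
- The LR screen's product score ignores receptor stoichiometry and
  multi-subunit complexes.
- The mean-variance HVG trend uses lowess with a fixed span (0.3);
  very small gene panels fall back to raw variance ranking.
- QC interprets "mitochondrial count > x%" as mitochondrial UMI
  fraction of total counts; the denominator was not defined in the
  source description.
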