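# Methods

`regulonkit` implements a consensus gene-regulatory-network (GRN) workflow
for comparing cell subpopulations of one cell type between two biological
conditions (e.g. control vs knockout mice). This note records the models,
the parameters that matter, what the bundled simulator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Preprocessing

Counts pass through a fixed, order-sensitive funnel:

1. **Cell QC** — keep cells with detected features > 200, mitochondrial
   fraction < 0.10 and total UMIs < 30,000 (the UMI cap removes likely
   doublets). Boundary semantics are literal: a cell at exactly 200
   features, exactly 10% mito or exactly 30,000 UMIs is removed. The
   mitochondrial fraction comes from cell metadata when present, else from
   genes matching a configurable prefix (default `mt-`).
2. **Gene-symbol hygiene** — genes ending in `Rik` or starting with `Gm`
   (configurable) are dropped. Matching is literal, so a legitimate symbol
   like `Gmds` is also removed; we document rather than special-case this.
3. **Contamination removal** — any cell with a nonzero count in any
   exclusion marker (default `Ptprc`, `Adgre1`) is removed. The pipeline
   also accepts externally supplied cell labels by filtering the input
   matrix before `run_all`.
4. **Cell/gene prevalence filter** — keep cells detecting strictly more
   than 300 and strictly fewer than 5000 genes, then genes expressed in at
   least 5 remaining cells (inclusive).
5. **Normalization** — counts scaled to 10,000 per cell, then ln(1+x).
6. **HVG selection** — per gene, mean and dispersion (variance/mean) of the
   expm1 values; dispersions z-scored within 20 equal-frequency mean bins
   (value-based bins, so equal means share a bin); a gene is selected iff
   0.0125 < log1p(mean) < 3.5 and its normalized dispersion ≥ 0.45. The
   binned-dispersion recipe is one of several consistent with the named
   thresholds; bin count and recipe scale are configurable.
7. **Cross-condition union** — HVGs are computed per condition and on the
   concatenated matrix, and their union taken, so both conditions share one
   feature space.
8. **Scaling** — per-gene z-score with *population* SD (the sample/population
   difference is negligible at hundreds of cells but must be fixed for
   bit-reproducibility); constant genes map to zero and are flagged.

The network gene space is the HVG union plus every candidate TF present in
the data: regulators must exist as predictor columns regardless of their own
dispersion rank.

## Network inference and consensus regulons

Per condition, each gene's scaled profile is regressed on all candidate TF
profiles (excluding itself) with stochastic gradient boosting (500 trees
maximum, learning rate 0.01, subsample 0.9, feature subsample 0.1, early
stop when the trailing 25-round mean out-of-bag improvement turns
negative). Edge importance is the gain-sum attributed to a TF; importances
are comparable only within one target's model. Fits iterate over cells in
canonically sorted cell-id order, so results are invariant to row order.

Modules keep, per TF, the union of the top-50 targets by importance and any
target above a global importance quantile (disabled by default); ties keep
the lexicographically smaller symbol. Motif-based pruning requires external
ranking databases, so modules are instead intersected with a user-supplied
TF→target evidence table (`prune_with_prior`); modules below 3 targets are
dropped, and TFs absent from the prior are dropped (conservative) or passed
through (permissive flag). **This is the one deliberate substitution in the
workflow** — everything downstream treats the pruned modules exactly as
motif-pruned regulons.

Inference runs `n_runs` times (default 20; the bundled benchmarks use 5)
with per-run derived seeds. Consensus regulons take the union of each TF's
targets over runs; targets are ranked by the fraction of runs containing
them (frequency), then mean importance, then symbol. Per-target
mean/median/SD of importance (over runs where present) and of normalized
expression (over the condition's cells) are attached.

## Activity scoring

A cell's genes are ranked by normalized expression (rank 1 = highest); ties
— including the zero bulk — break by a uniform shuffle seeded per cell id,
so subsetting cells never changes retained cells' ranks. With G genes, top
fraction f (default 0.05, the conventional default for recovery-AUC
scoring; configurable) and regulon R (intersected with the
gene space), T = ⌈fG⌉ and

    AUC = Σ_{k=1..T} h(k) / Σ_{k=1..T} min(k, |R|),  h(k) = |{g ∈ R : rank(g) ≤ k}|,

which is exactly 1 when R fills the top |R| ranks. Ranking uses the
normalized (never the scaled) matrix, over the full post-filter
transcriptome: gene-level scaling would destroy within-cell order, and
restricting the ranking to the network genes would change every score's
denominator.

## Subcluster extraction and alignment

Standardized (column z-scored) AUC matrices are clustered by average-linkage
(UPGMA) agglomeration on correlation distance (1 − Pearson; a constant
profile has correlation defined as 0). Both centered and uncentered
correlation are implemented; centered is the default. Tie-breaks are fixed:
among equal-height candidate merges, the pair whose sorted member-id tuples
compare lexicographically smallest merges first, and leaf order visits the
subtree with the smaller minimum member id first — making the dendrogram
exactly invariant to input row permutation.

The reference condition's regulons are clustered once and the other
condition's columns are permuted to that order (no second column
clustering), which is what makes the two heatmaps comparable. Subclusters
are extracted by cutting each cell dendrogram into k clusters (k supplied
per condition; subcluster boundaries are often read off heatmaps by eye,
and an explicit cut rule is the reproducible replacement for that), labels
numbered by leaf order.

For alignment, the two conditions' AUC matrices are intersected on shared
regulon TFs, stacked, column-standardized *after* concatenation, reduced by
PCA to 15 components (deterministic sign: each component's
largest-magnitude loading is positive) and embedded by UMAP (n_neighbors
30, min_dist 0.3, Euclidean, fixed seed). Identical input rows receive
identical coordinates (PCA transform is row-pure and duplicates are
collapsed before UMAP). Subcluster centroids are the mean 2-D coordinates
of member cells; matches are mutual nearest centroids across conditions; a
subcluster is unique iff it has no mutual match or its nearest
cross-condition distance exceeds 1.5× the largest matched distance (margin
configurable).

## Differential testing

**Regulons** — per regulon, a two-sided Wilcoxon rank-sum test on *raw* AUC
scores (the |ΔAUC| gate lives on the AUC scale), BH correction across
regulons, significant iff adjusted p < 0.05 AND |mean difference| > 0.15.
Matched subclusters are compared across conditions; a unique subcluster is
compared against all other cells of its own condition. The exact Wilcoxon
branch (n ≤ 16, tie-free) enumerates the null by a rank-sum recursion; the
normal branch uses the tie-corrected approximation with continuity
correction.

**Genes** — a hurdle model per gene: logistic regression of detection
(count > 0) on group, Gaussian regression of positive normalized values on
group; the two likelihood-ratio chi-squares add (df add) and the sum is
referred to the chi-square tail. With the default group-only design both
parts have closed-form MLEs (the logistic part reduces to the 2×2 detection
table), so the test is exact and vectorizes over genes. A per-cell
detection-rate covariate — the standard hurdle-model adjustment — is
available by flag (group-only is the default design), using
iterative fits with a ridge-penalized fallback under separation. Genes
detected in fewer than 3 cells are assigned p = 1 and flagged. Reported
DEGs must pass max(pct₁, pct₂) ≥ 0.15, |pct₁ − pct₂| ≥ 0.15, |log2FC| ≥
0.585 (fold change 1.5; pseudocount 1 on the expm1-mean scale) and
Bonferroni-adjusted p < 0.05, with the pct/LFC gates applied before testing
as speed filters and re-checked after. DETGs are a significant regulon's
targets intersected with the DEG list, ordered by consensus rank.

**Enrichment** — hypergeometric upper tail per gene-set term (log-space
summation), BH across tested terms, term sizes 3–2000 in the universe. The
universe is always caller-supplied because the workflow uses two different
universes (all DE-tested genes for DEG lists; the network gene space for
DETG lists).

## The synthetic-data generator

The generator is the testbed: two conditions sharing 3 subcluster activity
programs, condition A carrying one unique program, each program a binary
on/off vector over TFs. Where TF t is active, t's own mean and all its
targets' means multiply by `activity_effect`. Counts are gamma-Poisson
(negative binomial, Var = μ + 0.3μ²), per-cell depth factors log-normal
(σ = 0.3), and independent per-entry Bernoulli dropout (rate 0.1) supplies
the extra zero inflation the hurdle test assumes.

Design choices that matter and why:

- **Expression landscape.** 3000 non-variable ("flat") genes with per-gene
  log-normal baseline means (median 2.5 counts, rare high tail), planted
  TFs/targets log-uniform around 6 counts. Real transcriptomes are mostly
  lowly expressed genes with a thin highly-expressed tail; this shape is
  what anchors every HVG mean bin with flat genes and keeps the top 5% of a
  cell's ranking reachable by active regulon targets. With a degenerate
  single-mean flat background, the binned dispersion z-score and the
  recovery AUC both collapse for reasons that have nothing to do with the
  methods under test.
- **Program structure.** Per-TF activity patterns are sampled *distinct*
  from the pool of binary patterns that (i) vary across the shared programs
  and (ii) are active in at most half the programs. Two TFs active in
  exactly the same subpopulations are indistinguishable by co-expression; a
  TF constant within a condition, or active almost everywhere, has (almost)
  no between-population variance there. These are degeneracies of a planted
  design, not method failures, so the generator excludes them (duplicates
  are allowed only when the pool is smaller than the TF count). Shared
  programs are identical across conditions, making every matched-subcluster
  cross-condition contrast an exact null; the unique program differs from
  every shared program in ≥ 25% of TFs.
- **Contaminants.** `spike_contaminants` appends cells expressing every
  exclusion marker (≥ 1 count) over a Poisson draw around the gene means,
  recording their ids so the marker filter can be validated exactly.

What the generator does **not** emulate: batch effects, doublets beyond the
UMI cap's reach, gene length/GC bias, graded (non-binary) programs (an
option exists via non-binary activity values but defaults to binary),
cross-regulon regulatory cascades, or realistic mean–variance trends beyond
the single shared NB dispersion. Passing the planted-recovery benchmarks
therefore shows the machinery is correct and well calibrated under the
stated noise model — not that inference will reach the same accuracy on
real tissue.

## Problem sizes and seeds

The bundled benchmarks run the full workflow at the study conditions used
throughout the documentation: 150 cells per subcluster, 12 TFs × 20
targets, activity effect 4, 5 inference runs, exact prior, over three master
seeds; the determinism check uses a smaller configuration (6 TFs × 8
targets, 60 cells per subcluster, 2 runs, target_sum near the library size
of its reduced gene space) since bit-reproducibility does not depend on
problem size. Every random draw in the package flows from a single master
seed through SHA-256-derived per-stage seeds (`derive_seed`); no stage
touches global random state, and the hurdle calibration experiments (type-I
error on 1000 null genes at 150 cells/group; power at a planted 2-fold
effect and 40% detection) are seeded the same way.

## Known limitations

- The min.diff.pct gate has no signal for saturated genes: modules whose
  targets are detected in ~90% of cells in both groups yield no DEGs even
  under strong fold changes; this is inherent to detection-fraction gates
  on highly expressed genes.
- The normalized-mean HVG gates (0.0125, 3.5 on the log1p scale) assume a
  normalization target comparable to the library size of a ~10⁴-gene
  transcriptome; very small gene spaces need a proportionally smaller
  `target_sum` or every gene exceeds the upper gate.
- UPGMA on correlation distance is quadratic in cells and the UMAP step
  dominates wall time for > 10⁴ cells.
- The exact Wilcoxon branch is limited to n₁+n₂ ≤ 16 without ties; beyond
  that the tie-corrected normal approximation is used.
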