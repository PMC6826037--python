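# Methods

`mucocensus` implements the bespoke computational procedures of a
perturbation-robust analysis of branching airway-epithelium differentiation
in scRNA-seq: consensus clustering with stability scoring, distribution-
relative QC, two-pass normalization, one-vs-all Wilcoxon marker detection
with a pooled robustness design and rank-rank hypergeometric overlap (RRHO),
marker z-score annotation, double-positive (hybrid) cell quantification, and
pseudotime-window expression smoothing. A synthetic branching-differentiation
generator provides planted ground truth for every step.

## Clustering-robustness census

The census asks how reproducible a k-cluster partition of n cells is when
the dataset is perturbed. For each candidate k (default 2–9):

1. **Perturbed runs.** 10 subsets are drawn, each removing 10% of cells
   uniformly at random; each subset is clustered 10 times with distinct
   derived seeds, giving 100 runs per k. Seeds derive from the plan seed via
   `numpy.random.SeedSequence(seed, spawn_key=(k, subset, rep))`, so the
   census is bit-reproducible across platforms.
2. **Stability matrix.** S[i, j] is the fraction of runs, among those where
   cells i and j were both present, in which they received the same label.
   The diagonal is 1. Pairs never co-present (negligible probability at the
   default 100 runs × 10% dropout) get the uninformative prior 0.5 and are
   flagged.
3. **Consensus partition.** Rows of S are treated as feature vectors;
   average-linkage hierarchical clustering of their Euclidean distances is
   cut at k.
4. **Stability scores.** Per-cell stability is the mean S to the cell's
   own-cluster co-members (singletons score 1 by convention). Intra-cluster
   stability is the mean over within-cluster pairs, averaged unweighted over
   clusters; inter-stability is the mean over between-cluster pairs.
5. **Choosing k.** The average intra-stability curve peaks at the supported
   k: fewer clusters force merges that perturbed runs resolve
   inconsistently, more force arbitrary splits. `select_k` returns the
   interior argmax of the curve — the point visual inspection of the elbow
   plot picks. We evaluated second-difference "elbow" automations and found
   them fragile: the signed second difference selects one k past the drop,
   and its absolute value latches onto shoulder kinks produced by stability
   collapses at the far end of the k range. A flat or linear curve yields
   the smallest interior k plus a warning; `fit(k=...)` overrides the
   automation. The full intra/inter curves are always reported.
6. **Unassigned cells.** Cells with per-cell stability strictly below 0.70
   are flagged unassigned and should be excluded from population-level
   statements. Several per-cell stability formulas are defensible; this
   package uses the mean similarity to own-cluster co-members.

The base clusterer is pluggable (`base_cluster(expr, k, seed) -> labels`);
an external clusterer such as SIMLR can stand in, treated as a black box.
The default is log1p → top-30 PCA → k-means with 10 restarts. Ten restarts
matter: with a single restart most measured instability is k-means optimizer
noise rather than a response to the data perturbation, which depresses
per-cell stability (~0.91 on cleanly separated data versus ~0.99 with
restarts) without changing the selected k.

One stability matrix is built per k from that k's own runs. Pooling all
runs across k into a single matrix is superficially attractive but
self-defeating: same-type cells co-cluster at every k, so the pooled
within-type stability stays ~1 no matter how a block is over-split and the
intra-stability curve loses its elbow.

## QC and normalization

Per-cell metrics are the number of expressed features (genes with ≥ 1 UMI),
dropout percentage (1 − features/genes), library size (total UMI) and
mitochondrial fraction (UMI share on `MT-`-prefixed genes,
case-insensitive). Cells strictly above the 95th or strictly below the 5th
empirical percentile (linear-interpolation quantiles) of the first three
metrics, or strictly above the 95th percentile of the mitochondrial
fraction, are removed. All four rules are evaluated jointly on the
unfiltered distributions rather than sequentially — joint application
keeps the report interpretable, and a cell can carry several removal
reasons. Strict inequalities mean a fully tied distribution removes
nobody. Genes must be detected (≥ 1 UMI) in at least five cells.

Normalization is two-pass. Pass 1 divides each cell by library size /
median library size ("median UMI counts as a scaling factor"). Pass 2,
available once cluster labels exist, computes a per-cluster per-gene
reference (mean of pass-1 values) and a residual per-cell factor as the
median, over ~20 expression bins, of the ratio of the cell's binned sums to
the reference's binned sums, rescaled to mean 1. Binned sums rather than
per-gene ratios are essential at single-cell depth: per-gene ratios
restricted to a cell's detected genes are biased by dropout (deep cells
look systematically shallow), and in our tests the per-gene variant failed
to equalize a planted 2× library-size inflation of one cell type while the
binned variant removes it to within 5%. Clusters under 3 cells fall back to
pass-1 factors. The log layer is natural-log(1 + x).

Highly variable genes: 20 equal-occupancy mean-expression bins, dispersion
= variance/mean z-scored within bins, top n (200–500 typical) by z with
deterministic ties by gene id; constant genes are never selected.

## Marker detection, pooled robustness, RRHO

`wilcoxon_rank_sum` is a two-sided rank-sum test returning the rank-sum W
of group 1. For tie-free pooled samples of ≤ 12 observations the p-value is
exact, from the full distribution of W (a subset-sum dynamic program,
verified in tests against explicit enumeration of all rank splits);
otherwise a normal approximation with the standard tie-correction of the
variance and a 0.5 continuity correction. Identical samples give p = 1.

`find_all_markers` tests every gene one-vs-rest per cluster (prefilter:
detected in ≥ 10% of the cluster or of the rest), with Benjamini–Hochberg
adjustment within each cluster over its tested genes. log-fold-change uses
natural log with pseudocount 1 on mean normalized expression, matching
the Seurat convention. Tables sort by
(cluster, FDR, |logFC| descending).

`pooled_de` implements the robustness design: per repetition, 100 cells
from the target cluster versus an equal mixture of the other clusters
(balanced shares, remainder distributed round-robin in cluster order) or a
same-size pool of one other cluster. Ten repetitions by default; rankings
are compared with `rrho`, whose map entry at rank
thresholds (i, j) is −log10 of the exact hypergeometric upper tail
P[X ≥ |top-i ∩ top-j|] with population N, i successes, j draws, clipped at
320. The pooled/RRHO path is deliberately conservative — it favors highly
expressed genes that resist dropout — so the per-cell Wilcoxon test is
the default; both are implemented.

## Annotation

For each candidate type, a cell's raw score is the mean normalized
expression of the type's markers (missing genes dropped with a warning; at
least 5 usable genes required). Scores are z-scored per type across cells —
following the cell-cycle phase-scoring convention; the
alternative reading (per cell across types) is available via
`z_across="types"`. Assignment is argmax z with ties broken by raw score
then type name. Cluster annotation is the modal member assignment, labeled
ambiguous under 50% agreement.

## Hybrid quantification and smoothing

Positivity is either "detected" (normalized value > 0, the default for
quantification) or "percentile" (strictly above the median of the gene's
positive cells — the top-50-percentile rule used for single-gene display).
The double-positive fraction divides cells positive for both genes by
either the union of single-positives ("either", i.e. the share of the
GC-and-MCC union population), all cells, or an explicit subset, with a
Clopper–Pearson 95% CI. The positivity rule materially affects the
estimate, which is why both rules are exposed rather than hard-coded.

Heatmap ordering sorts cells by branch, then cluster emergence (rank of the
cluster's median pseudotime), then pseudotime, ties by barcode. Smoothing
z-scores each gene across cells (population SD, denominator n; zero-
variance genes → 0, flagged), then applies a centered moving average of
width 10 along the ordering, truncated symmetrically at segment ends and
never crossing branch boundaries.

## Synthetic data generator

The generator emulates the structure of an airway differentiation time
course at validation scale: a lineage tree (default cycling basal → basal →
suprabasal → club → {goblet | deuterosomal → multiciliated}; a six-type
variant folds cycling basal into the root, and a goblet→MCC two-type
lineage models the population over which double-positive shares are
measured), per-type occupancies, pseudotime intervals on [0, 1] and branch
labels. Counts are negative binomial with mean = cell scale ×
type/pseudotime-dependent gene mean and dispersion α = 0.5 (variance
μ + αμ²); dropout is the NB mass at zero, with no separate zero-inflation
layer. Library scales are lognormal (σ = 0.35, normalized to mean 1).
Baseline gene means are lognormal (median 0.2). Two percent of genes are
mitochondrial (`MT-` prefix); an option plants a fraction of high-mito
cells for QC tests. Gene ids are `G000001`-style, barcodes
`cell_000001`-style.

Each type has 15 planted markers elevated 8-fold when the type's module is
active. The first marker of each set is a *sentinel*: baseline 0.005,
fold 1600 — a near-binary canonical marker in the mold of MUC5AC or FOXJ1,
whose off-lineage detection is ~0.5%. Ordinary fold-8 markers are detected
in ~17% of off-type cells, so without sentinels any detected-rule
double-positive count is dominated by chance doubles; canonical markers in
real airway data have exactly this high-expression/high-specificity
profile. Marker modules activate along pseudotime with a logistic rise
(width 0.01) at the stage start and a steeper logistic decay (width 0.004)
centered on the stage end; the root module needs no rise and terminal
modules do not decay. This hand-off leaves no low-expression dead zone at
stage boundaries (which the census would legitimately detect as extra
clusters) while guaranteeing that no pure cell carries two modules at
≥ 50% activation — that signature is reserved for hybrids.

Hybrid cells model goblet→MCC intermediates: a configurable fraction of
cells (Binomial per cell, or an exact count ⌊fraction × n⌋ for
deterministic tests) is assigned to the transition's two types with both
marker modules activated independently at Uniform(0.5, 1). The fraction is
interpreted relative to all simulated cells; the double-positive validation
therefore simulates the goblet+MCC population itself (the two-type
lineage), since that is the population such shares are quoted over.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, cell-cycle structure, spliced/unspliced layers, and realistic gene
counts (1,000 genes versus ~20,000). Passing tests demonstrate that the
procedures recover planted structure under NB noise and dropout at
validation scale (600–1,000 cells), not that they are robust to artifacts
the generator omits.

## Validation sizes and numerical conventions

The package validates itself on 600-cell/6-type/1,000-gene datasets for
clustering and markers, and 1,000-cell datasets for annotation and hybrid
shares. Quantile filtering uses linear-interpolation empirical quantiles;
z-scores use population SD; BH is applied within cluster over tested genes;
RRHO entries are clipped at 320; the unassigned threshold 0.70 is strict
(a score of exactly 0.70 is assigned); consensus ties in hierarchical
clustering follow SciPy's deterministic linkage order; k-means uses 10
restarts with seeds derived from the plan seed.

## Known limitations

- The census is O(runs × n²) in memory and time for the stability matrix;
  beyond ~10⁴ cells the matrix should be built in blocks.
- The elbow automation assumes the intra-stability curve has an interior
  maximum; on unstructured data it returns the smallest interior k with a
  warning rather than "no clusters".
- Pass-2 normalization assumes clusters are large enough (≥ 3 cells) to
  define a reference; very small clusters keep pass-1 factors.
- The exact Wilcoxon path requires tie-free data; UMI-derived values are
  tie-rich, so the tie-corrected normal approximation is what marker
  detection uses in practice.
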