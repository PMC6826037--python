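# mucocensus

Perturbation-based consensus clustering and marker analysis for branching
airway-differentiation scRNA-seq.

Airway epithelium regenerates through a branching lineage — cycling basal →
basal → suprabasal → club → {goblet | deuterosomal → multiciliated} — and
single-cell analyses of that process face two recurring questions: *how many
cell states does the data actually support*, and *are apparent intermediates
(e.g. MUC5AC⁺/FOXJ1⁺ cells between goblet and multiciliated fates) real or
clustering noise*? `mucocensus` implements a reusable, tested version of the
bespoke procedures built for this problem:

- **Clustering-robustness census.** For each candidate number of clusters
  k, cells are re-clustered on many perturbed subsets (10 subsets × 10%
  cells dropped × 10 seeded runs). The runs pool into an n × n stability
  matrix S, where S(i, j) is the frequency with which cells i, j co-cluster
  when co-present. Average-linkage hierarchical clustering of the rows of S
  gives a consensus partition; the elbow of mean intra-cluster stability
  over k selects k; cells with own-cluster stability < 70% are flagged
  *unassigned*. The base clusterer is pluggable (default: log1p → 30 PCs →
  k-means).
- **QC and normalization** — distribution-relative filters (5%/95%
  percentiles of features, dropout, library size; 95% of mito fraction),
  the ≥ 1 UMI in ≥ 5 cells gene filter, two-pass median-ratio
  normalization, and dispersion-based highly-variable-gene selection.
- **Marker detection** — one-vs-all Wilcoxon rank-sum per gene (exact for
  small tie-free samples, tie/continuity-corrected otherwise) with BH
  adjustment; a pooled robustness design (100-cell pools, 10 repetitions)
  and rank-rank hypergeometric overlap (RRHO) to compare rankings.
- **Annotation** — marker-set mean expression z-scored across cells; argmax
  assignment per cell, modal assignment per cluster.
- **Hybrid quantification** — double-positive fractions under explicit
  positivity rules ("detected" or top-50-percentile) with Clopper–Pearson
  CIs.
- **Pseudotime smoothing** — cells ordered by branch → cluster emergence →
  pseudotime; per-gene z-scores averaged over 10 neighboring cells, never
  across branch boundaries.
- **Synthetic generator** — negative-binomial branching-differentiation
  data with planted types, markers, library sizes, mito content and
  hybrids, used as ground truth throughout the test suite.

The census is exposed statsmodels-style: a `ClusterStabilityCensus` model
object whose `fit()` returns a `CensusResults` with labels, stability
diagnostics and a `summary()` table.

## Worked example

```python
import mucocensus as mc

lineage = mc.airway_lineage(cycling_root=False)   # 6-type tree
program = mc.ExpressionProgram.build(lineage, n_genes=1000, seed=7)
matrix, truth = mc.generate_counts(
    lineage, program, n_cells=600, hybrid_fraction=0.0, seed=11
)
norm = mc.normalize(matrix)

census = mc.ClusterStabilityCensus(norm, mc.PerturbationPlan(seed=1))
result = census.fit()
print(result.summary())
```

```
Clustering-robustness census
============================================================
cells: 600    runs/k: 100    drop fraction: 0.10
selected k: 6

  k    intra    inter
  2   0.9986   0.0014
  3   0.9829   0.0152
  4   0.9398   0.0446
  5   0.9830   0.0046
  6   0.9976   0.0005 *
  7   0.8377   0.0016
  8   0.8135   0.0017
  9   0.7430   0.0209

mean per-cell stability (k=6): 0.9969
unassigned (< 70%): 2 cells
```

Intra-cluster stability stays near 1 up to k = 6 — the number of planted
types — and collapses beyond it as the census is forced to split real
populations arbitrarily; the consensus partition at k = 6 matches the
planted types with ARI 0.97. Cells below the 70% stability threshold are in
`result.unassigned`, and `result.to_frame(matrix.barcodes)` exports labels,
stability and flags per cell.

Quantifying hybrid (double-positive) cells from the shell, on a simulated
goblet+MCC population with 89 planted hybrids among 1000 cells:

```yaml
# sim.yaml
lineage: gc_mcc
n_cells: 1000
hybrid_fraction: 0.089
exact_hybrid_count: true
```

```bash
mucocensus simulate --config sim.yaml --out data --seed 7
mucocensus hybrids --in data --gene-a G000001 --gene-b G000016 --rule detected
```

```
G000001+/G000016+: 9.3% (89/957; 95% CI 7.5-11.3%)
```

`G000001`/`G000016` are the planted goblet and multiciliated sentinel
markers (the MUC5AC/FOXJ1 analogues); 89 of the 957 cells positive for at
least one of them are positive for both, and the planted 8.9% share lies
inside the exact 95% confidence interval.

Other subcommands: `mucocensus qc`, `census`, `markers`, `annotate`,
`smooth` — each a thin wrapper over the corresponding library function,
reading 10x triplet directories or dense TSV and writing TSV tables.

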