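# rootatlas

Analysis toolkit for single-cell RNA-seq atlases of the plant root: cell-type
annotation by rank correlation to a deconvolved reference expression map,
principal-graph trajectories with pseudotime, spatial-autocorrelation
(Moran's I) tests for cluster-specific genes, promoter motif enrichment with
exact PWM match p-values, total-mRNA trend statistics with a gene-set slope
permutation test, and negative-binomial differential expression between
control and heat-shocked cells aligned by mutual nearest neighbors.

The package ships a first-class synthetic-data generator that reproduces the
statistical structure these analyses assume — cell-type programs with marker
genes, smooth developmental gradients per type, NB-distributed UMI counts
with variable library sizes, a hair-like lineage whose total mRNA declines
across developmental stages, a heat-shock condition with a shared stress
program and marker repression, and promoters with planted motifs — so every
stage is testable end to end without any external download.

## The methods in brief

- **Annotation.** For cell *c* and reference column *r* (a cell type ×
  longitudinal zone), compute Spearman's ρ(c, r) over a highly-variable gene
  set; assign *c* the argmax column (`endodermis_11`-style labels).
- **Trajectories.** A principal tree (refined-landmark minimum spanning
  tree, SimplePPT-style) is fitted in embedding space; pseudotime is the
  geodesic distance from a root node chosen as the node whose cells carry
  the earliest developmental-zone annotation.
- **Specific genes.** Moran's I = (N/ΣW)·(Σᵢⱼ wᵢⱼzᵢzⱼ)/(Σᵢzᵢ²) over a 25×25
  grid of the 2-D embedding with rook weights, permutation p-values, BH
  q-values, and a Jensen–Shannon specificity score; calls require
  I > 0.1, q < 0.05, specificity > 0.7.
- **Motifs.** 500-bp promoters scanned on both strands with log₂-odds PWM
  scores; match p-values are exact tail probabilities from a lattice
  dynamic-programming convolution of the background score distribution,
  cutoff 1e-5; per-set frequency vs. genome background gives
  log₂((f_set+ε)/(f_bg+ε)), and early/late calls use a mean + 1.5·sd rule.
- **Total-mRNA trend.** Cells are binned into equal-count pseudotime bins;
  the observed OLS slope of per-bin median gene-set totals is compared with
  10,000 random same-size gene sets: p = (#{null ≥ observed}+1)/(n_perm+1).
- **Differential expression.** Per gene, a likelihood-ratio test between
  nested negative-binomial GLMs (log link, size-factor offset, per-gene ML
  dispersion), per cluster with ≥15 cells in both arms; BH across all
  gene × cluster tests; significance at FDR < 0.1% and |log₂FC| > 1.

## Worked example

```python
import numpy as np
from rootatlas import simulate as sim, preprocess as pp, annotate as ann, mrna

config = sim.SimConfig(seed=1)            # 5 types x 4 stages, 2,000 cells
ref = sim.simulate_reference_map(config)
matrix, truth = sim.simulate_cells(config, ref)

factors = pp.size_factors(matrix)
hvg, _ = pp.select_high_dispersion_genes(matrix, factors, n=1500)
corr = ann.correlate_cells_to_reference(matrix, ref.reference, hvg)
ident = ann.assign_identity(corr)
acc = (ident.table.cell_type.to_numpy() == truth.cells.true_type.to_numpy()).mean()
print(f"annotation accuracy: {100 * acc:.1f}%")

hair = matrix.subset_cells((truth.cells.true_type == "hair").to_numpy())
stages = truth.cells.true_stage[truth.cells.true_type == "hair"].to_numpy(float)
geneset = truth.genes_with_role("stage-gradient", "hair")
res = mrna.geneset_slope_permutation_test(hair, geneset, stages,
                                          n_perm=10000, seed=2)
print(f"gene-set trend: slope {res.observed_slope:.1f}, p = {res.p:.2e}")
```

prints

```
annotation accuracy: 100.0%
gene-set trend: slope -0.1, p = 1.00e-04
```

Every cell recovers its true type at a marker fold of 8.  In the hair
lineage, total mRNA declines 4-fold across stages while the stage-graded
gene set holds essentially flat (slope ≈ 0) against that decline — no random
gene set of the same size comes close, so the permutation p-value sits at
its floor 1/10,001 ≈ 1e-4.

The same stages are available as an `atlas` command line
(`atlas simulate | preprocess | cluster | annotate | trajectory | specific |
motifs | mrna-trend | heatshock`); all stages are byte-deterministic given a
seed.

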