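# Methods

This note documents the models, algorithms, parameter choices and
limitations behind `rootatlas`, in the order the pipeline runs.

## Synthetic data model

The generator (`rootatlas.simulate`) emulates a root single-cell atlas with
`n_types` cell types, each traversing `n_stages` developmental stages
(longitudinal zones).  Expression means live in a reference matrix of shape
genes × (types·stages):

- per-gene baselines are lognormal(μ = ln `base_mean`, σ = 0.75); the
  default `base_mean` 0.5 over 5,000 genes yields a few thousand UMIs per
  cell, the order observed in droplet scRNA-seq of root protoplasts;
- **marker genes** of type *t* have exactly `marker_fold` × baseline in all
  of *t*'s columns (default 8, the regime where rank-correlation annotation
  is reliable but not trivial);
- **stage-gradient genes** of type *t* rise geometrically from baseline to
  `stage_gradient_fold` × baseline across *t*'s stages;
- **heat-shock program genes** are flat in the reference and respond only to
  treatment.

Cells draw a (type, stage) uniformly; the chosen reference column is scaled
by a lognormal library factor (σ = `libsize_lognormal_sigma`, default 0.3)
and, in the designated hair-like lineage (always the first type), by
`mrna_decay_fold^(-(stage-1)/(n_stages-1))`, producing the lineage-wide
total-mRNA decline the trend statistics target.  Counts are negative
binomial in the mean/size parameterization with a size parameter shared
across genes (`nb_dispersion`, default 2; `inf` gives Poisson).  Because
the decay multiplies every gene in the lineage, a stage-graded gene's
*observed* counts rise only when its gradient outpaces the decay; the
trend-recovery conditions therefore use gradient fold 16 over decay fold 4
(net 4-fold rise), mirroring hair-marker genes that gain expression while
total mRNA falls.

Heat shock redraws a treated cohort from perturbed means — stress-program
genes × `hs_up_fold`, markers ÷ `marker_down_fold` — leaving control cells
untouched; an optional map of gene → (type, fold) perturbs genes in a single
type to plant cluster × treatment interactions.  Promoters are i.i.d.
uniform A/C/G/T (the null under which exact match p-values are calibrated);
designated gene sets receive a motif's consensus at a uniform position and
strand with a per-set plant probability.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects beyond the treatment contrast, dissociation-induced stress
artifacts, realistic gene identifiers, or non-uniform genomic base
composition.  Passing tests therefore demonstrate correctness of the
statistical machinery under its stated assumptions, not robustness to these
real-data nuisances.

## Normalization and projection

Size factors are total UMIs divided by the geometric mean of totals over
nonzero cells; zero-total cells are flagged NaN and excluded downstream
rather than imputed.  Gene selection uses the method-of-moments NB
dispersion (var − mean)/mean² of normalized counts, ranked against a fitted
trend `dispersion ~ a + b/mean` (ordinary least squares on genes with
positive dispersion); the top 1,500 by ratio are kept, ties broken by gene
id.  Projection is PCA of gene-centered log1p normalized expression
(pseudocount 1 throughout the package); component signs are fixed from the
largest-magnitude gene loading so results are equivariant under cell
permutation.  No expression floor is applied below the log transform.

## Clustering and embedding

The neighbor graph connects mutual k-nearest neighbors (default k = 50,
cosine metric) weighted by similarity (1 − cosine distance, clipped to
(0, 1]).  Communities come from the Louvain algorithm (igraph
`community_multilevel`) with the RNG seeded per call; labels are contiguous
from 1.  The 2-D embedding is UMAP with n_neighbors = 50, min_dist = 0.1,
cosine metric and a fixed random state; re-clustering a cell subset with
other parameters (e.g. min_dist 0.05, n_neighbors 25) is the same code path
on the subset.  The embedding is a pluggable contract — any
neighbor-preserving method satisfies the downstream tests.

## Annotation

Spearman correlations are computed on average-tie ranks of raw counts:
rank statistics are invariant to any per-cell monotone normalization, so
normalizing first would not change the result; Pearson mode uses log1p of
size-factor-normalized counts.  The identity is the argmax reference column
with a first-in-file-order tie-break (ties flagged); the runner-up column is
recorded as a perturbation diagnostic.  Cells with zero variance over the
gene set, or all-NaN correlations, carry a sentinel `unassigned` label and
stay in the tables to keep matrices aligned.  Marker k-means signatures
(k = 7 by default, k-means++ with 10 restarts, fixed seed) and pseudo-bulk
vs. bulk comparisons (log(x+1) summed counts; squared Pearson and Spearman)
are independent annotation diagnostics; agreement between routes is
reported, not enforced.

## Trajectories and pseudotime

The principal graph is a refined-landmark MST: k-means landmarks are
iteratively moved to the mean of their assigned cells (mean-shift, stop when
the largest move is < 1e-4 of the data scale), unoccupied landmarks are
dropped, a Euclidean minimum spanning tree connects the rest, and every cell
projects to its nearest tree edge.  This deliberately implements the
geometric core of reversed-graph-embedding trajectory learners rather than
the full elastic-energy optimization; the properties the pipeline consumes —
order recovery along gradients, branch-point detection — are what is tested.
The root is the node whose projected cells have the smallest mean stage
annotation (ties: more annotated cells, then lower node id), with an
explicit override available.  Pseudotime is geodesic distance along the tree
from the root to each cell's projection; on a tree this is
min(d(root,u)+offset, d(root,v)+length−offset) for a cell on edge (u,v).
Degenerate inputs (all cells identical) yield a single-node graph with zero
pseudotime.  A branch is the subtree hanging off a degree-≥3 node; the side
branch is the subtree with the fewest projected cells.

Branch-specific genes pass three filters: Jensen–Shannon specificity > 0.8
between branch and main mean expression, detection in ≥10% of the cells
considered, and mean normalized expression > 0.25 (all configurable).

## Moran's I specificity

The embedding's bounding box is cut into `nbins` × `nbins` equal-width units
(default 25); occupied units keep rook adjacency with weight 1.  Per-unit
values are means of log1p size-factor-normalized expression.  Moran's I uses
the standard double-sum form; p-values come from permuting unit values
(default 999 permutations, one-sided for positive autocorrelation,
(b+1)/(n+1) counting) — exact under exchangeability, rather than the normal
approximation, and the choice is exposed.  BH q-values are computed over
tested genes; zero-variance genes are flagged and excluded from the family.

Specificity is 1 minus the base-2 Jensen–Shannon *distance* between the
gene's per-group mean-expression distribution and the indicator of its best
group, computed on linear (not log) normalized means — log compression would
flatten the distribution and make the 0.7 threshold unreachable even for
strongly specific genes.  Under this convention a gene expressed in exactly
one group scores 1; a gene uniform over g ≥ 2 groups scores ≤ 0.56.  A
fold-8 marker over an expressed baseline scores ≈ 0.67 — *below* the 0.7
bar — so the planted-recovery tests use near-exclusive markers (fold 50),
the regime of GFP-line marker genes the threshold was designed for.  Calls
require I > 0.1, q < 0.05 and specificity > 0.7.

## Motif scanning and enrichment

PWMs are read from JASPAR-like text with a 0.5 pseudocount per cell before
per-position normalization (avoids −∞ log-odds).  Scanning scores each
window by the sum of per-position log₂(p/background) values discretized to a
0.01 lattice; the null score distribution is built by dynamic-programming
convolution on that lattice, so the reported p-value of a score is its exact
tail probability under the background (discretization error ≪ the 1e-5
cutoff; zero-probability bases are excluded exactly, giving degenerate
consensus-only PWMs the exact p = ∏ background probabilities).  Both strands
are scanned by default (the reverse-complement matrix scans forward, keeping
coordinates left-anchored); windows containing N are skipped.  One practical
consequence of exactness on a uniform background: a motif shorter than 9 bp
cannot reach p ≤ 1e-5 (0.25⁸ ≈ 1.5e-5), so planted-motif studies use
length-10 motifs.

Enrichment counts promoters-with-≥1-hit, not total hits: frequency per gene
set vs. the all-promoter background, log₂((f+ε)/(f_bg+ε)) with
ε = 1/(2·n_promoters) so absent motifs give 0, not −∞.  Early/late calls
require a motif's frequency to exceed the across-motif mean by 1.5 sd
(sample sd, configurable multiplier) and to beat the opposite stage.
Transcription-factor families aggregate by max enrichment over member
motifs via a user-supplied id → family table.

## Total-mRNA trend and permutation test

Cells sorted by pseudotime are split into contiguous equal-count bins
(sizes differ by ≤1; default 20 bins — the slope sign is stable across
10–50 bins on the synthetic lineage).  The gene-set statistic is the
per-bin median of per-cell summed counts over the set; the slope is OLS of
bin medians on bin mean pseudotime (the Gaussian-identity GLM — the
simplest reading of a "generalized linear model" slope).  The null re-draws
`n_perm` same-size gene sets uniformly without replacement from all genes;
p = (#{null ≥ observed}+1)/(n_perm+1), so p is never 0 and equals exactly
1/10,001 at 10,000 permutations when no null slope reaches the observed one.
Summing-then-taking-medians (rather than medians-of-medians) is the
documented reading of "median total mRNA of a random sampling".

## Heat-shock differential expression

MNN alignment removes the condition-wide embedding offset: the global mean
difference is subtracted first (nearest-neighbor pairing is blind to a
rigid translation — matches shift index-wise — so the translation must be
handled globally), then mutual nearest-neighbor pairs define correction
vectors that are Gaussian-kernel smoothed (bandwidth = median pair-vector
norm, down-weighting loose boundary pairs) and applied to treated cells as
zero-mean local corrections, iterating until the mean correction falls
below 1e-3 of the data scale.  Identically distributed conditions receive a
near-zero correction; a constant shift is removed essentially completely.

Per gene, differential expression is a likelihood-ratio test between nested
NB GLMs with log link and log-size-factor offset.  The dispersion α
(var = μ + αμ²) is estimated per gene by maximizing the NB likelihood at
Poisson-fitted means (bounded search on log α, floor 1e-6) and then held
fixed in both fits; the LRT statistic is referred to χ² with df = the
difference in parameter counts.  Non-converging genes are flagged NaN and
excluded from the BH family.  Fold changes are log₂ of (mean+1) normalized
expression ratios rather than GLM coefficients — robust for genes with
many zeros and consistent with heat-map thresholding.  Per-cluster tests
run only in clusters with ≥15 cells in both arms (skipped clusters are
recorded); BH is applied across all gene × cluster tests jointly, and
significance needs FDR < 0.1% and |log₂FC| > 1.  Upset-style summaries
count, for each exact cluster combination, the genes significant in
precisely that set.  The "Treatment within cluster" and
"Treatment×Cluster vs Cluster" designs are both provided, matching the two
uses of the test (per-cluster response and interaction).  Size factors are
computed jointly over both samples, which stands in for library
equalization between runs.  Gene signatures use Ward linkage (scipy `ward`,
the ward.D2 criterion) on standardized log1p-normalized profiles, cut into
k = 8 groups, with per-cell mean log-normalized expression per group.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run everything at desk scale:
2,000 cells × 5,000 genes for annotation, 500–1,000 cells for trend and
pseudotime recovery, 10,000 permutations for the slope test, 1,000 random
grids for the Moran oracle, 2,000 null + 100 planted genes at 200 cells per
arm for DE calibration — sizes chosen so each stage completes in seconds to
a couple of minutes on one CPU while keeping every statistical margin wide.
All randomness flows through explicit seeds; identical configuration and
seed give byte-identical outputs at every CLI stage.

## Known limitations

- The principal graph is a geometric approximation; it does not optimize
  the reversed-graph-embedding objective and can misplace branch points on
  very noisy data.
- Per-gene ML dispersion with a floor replaces the dispersion-sharing of
  established DE frameworks; with very few cells per cluster the LRT grows
  conservative (type-I ≈ 0.04–0.05 at nominal 0.05 in our calibration).
- Total-count size factors are compositional: if a large fraction of the
  transcriptome changes, fold changes of unchanged genes shift; the DE
  thresholds assume the perturbed fraction is modest.
- Exact PWM p-values assume an i.i.d. background; real promoter composition
  is handled only through the supplied background vector.
- Pseudotime units are arbitrary (tree edge lengths in embedding space);
  only order and branching structure are meaningful.
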