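# Methods

`ontotree` reimplements, at desk scale and with full ground truth, the
computational machinery used to turn a whole-embryo single-cell time series
into a rooted cell-type graph: doublet removal, mutual-nearest-neighbour
(MNN) edge inference, four-phase transition-gene nomination, perinatal
shift detection, and whole-embryo growth modeling. This note records the
models, the defaults that matter, and the places where the design was
genuinely open.

## Shared embedding conventions (`core`)

All neighbour statistics run in a PCA embedding built with one rigid
recipe: depth-normalize UMI counts to `ln(1 + c·s/total)` (default target
sum `s = 10,000` — the total-count normalization leaves the target sum
open, so it is a parameter), select highly variable genes (default 2,500,
capped at the number of non-constant genes; flavors: variance of the
log-normalized values, or variance/mean dispersion on the linear scale),
scale each gene to zero mean and unit variance, and project on the top 30
principal components. Three conventions exist purely for reproducibility
and are load-bearing for the test oracles:

* kNN search is exact Euclidean with ties broken by ascending cell index;
* each principal component's sign is fixed by making its largest-magnitude
  loading positive;
* HVG ranking breaks ties by gene id.

MNN pairs come in two modes. *Global*: a pair survives iff each cell is in
the other's kNN computed over all cells — this is the mode behind edge
scores, phase groups and dataset bridging. *Cross-group*: the kNN of each
A-cell is searched among B-cells only (and vice versa) — used for
progenitor mapping, where the question is "which pool cell is most like
this derivative cell", not "are these cells neighbours at large".

Graph communities use Leiden (RB-configuration, seeded) or igraph's
multilevel Louvain; Louvain has no seed argument, so the global igraph RNG
is seeded around the call. The voxel-probability smoother averages each
point's k nearest values (self included, `k = round(ln n)`) and min-max
scales to [0, 1]; a constant input maps to all zeros by convention.

## Synthetic embryo series (`synthdata`)

The generator emulates the statistical structure the pipeline assumes, not
embryo biology. Cell types are disjoint gene programs (default 30 genes at
8-fold enrichment over a lognormal baseline, sd 1.0 in log space) arranged
on a known lineage tree; each type is alive in a birth window on the time
axis. Per cell, relative expression is the normalized weight vector, the
library size is lognormal with median calibrated to ~2,700 UMIs per
nucleus, and counts are negative binomial (dispersion 1.5). Bit-identical
reproducibility from `SimConfig.seed` is a contract, tested.

Structural features with ground-truth labels:

* **Bridge cells** populate each parent→child transition at the child's
  birth timepoint. A bridge's log-mean program interpolates parent and
  child with mixing weight u ~ Uniform(0,1), and its observed label is the
  parent for u < 0.5, the child otherwise. The per-cell bridge probability
  at birth is scaled by the type's expected size over its birth-bin size,
  so `bridge_fraction` is exactly the fraction of the type's cells placed
  on the transition. Concentrating bridges at the birth bin is what makes
  edge time profiles peak at the transition time.
* **Doublets** are element-wise sums of two same-timepoint cells,
  binomially thinned to a freshly drawn library size. A `heterotypic`
  mode forces the two sources to differ in type — the configuration of the
  doublet-removal benchmark, since homotypic doublets are invisible to any
  expression-based detector by construction.
* **Abrupt types** swap their program for a disjoint, auto-generated
  replacement at the final timepoint only, mimicking a birth-triggered
  state switch; drift genes ramp linearly in log space for the gradual
  control.
* **Planted drivers** mark one parent→child edge: an *early* driver is
  upregulated (by `ln_fc` in log space) in parent-side bridge cells only,
  a *late* driver in settled child cells only, an *internode* driver in
  child-side bridges and settled children. Driver genes must not collide
  with any program (validated), since program interpolation would confound
  the planted effect.

What the generator does **not** emulate: ambient RNA, batch chemistry
effects, cell-cycle structure, within-type substates, gene-gene
correlation beyond programs, or realistic gene counts (the default gene
space is 1,000–2,000 genes so that programs dominate the variance the way
the top HVGs do in real data). Passing benchmarks therefore demonstrate
the *logic* of each procedure under its own assumptions, not performance
on real tissue.

## Doublet removal (`qc_doublets`)

Step 1 scores each cell with a simulated-doublet kNN classifier: 2n
artificial doublets (sums of random observed pairs, thinned to an observed
library size) are co-embedded with the observed cells (HVGs above the 85th
variance percentile, PCA 30 fitted on observed cells only), and each
observed cell's neighbour fraction q of simulated doublets (k = 30·(1+r),
add-one smoothed) is converted to a posterior doublet probability
`q·ρ/r / (q·ρ/r + (1−q)(1−ρ))` with prior ρ = 0.06 (the expected doublet
rate) and simulation ratio r = 2. Two choices here deserve comment:

* the posterior form, not the bare likelihood ratio, is essential — a cell
  whose neighbourhood contains simulated doublets merely in proportion to
  their 2:1 oversampling (q = 2/3) scores ρ, not ½, which is what makes
  the published 0.2/0.15 thresholds meaningful for singlets;
* thinning the simulated doublets matters — an unthinned sum is an
  *average* of two cells after depth normalization, with ~1/√2 their
  sampling noise, and such artificially quiet homotypic doublets pile into
  dense cluster cores and inflate singlet scores.

Step 2 clusters (top-3,000 HVGs, PCA 30, 50 neighbours, Louvain at
resolution 1), subclusters each cluster at resolution 3, and flags
subclusters whose step-1 doublet fraction exceeds 15% (strictly greater).
Step 3 targets doublets hiding in rare clusters: reclustering on the top
5,000 most dispersed genes (PCA 50), top-10 marker panels per cluster
ranked by one-vs-rest AUROC (fraction-expressing ≥ 0.1), per-cluster
re-embedding on the combined marker panel (PCA 10), subclustering, and
flagging subclusters whose mean own-panel score falls below the cluster's
0.25 quantile while the best other-panel score exceeds the 0.75 quantile.
Because clustering here operates on the kNN graph in PCA space rather than
in a 2-D UMAP, the resolutions default to graph-scale values (1.0 / 3.0);
the original procedure's tiny resolutions are an artifact of clustering in
a compressed 2-D layout. The final cell filters (UMI < 200, genes < 100,
unmatched rate ≥ 0.4 when present, score > 0.15, ribosomal% > 5,
mitochondrial% > 10) are applied after the union of the three flags, with
a per-rule removal ledger. Embryo sex is assigned by comparing total Xist
reads with total chrY-gene reads per embryo; ties are "ambiguous".

On the benchmark (two separable types, 6% spiked heterotypic doublets,
~10k cells), the union of the three steps removes ≥ 80% of spiked doublets
while touching ≤ 5% of singlets, across seeds.

## Cell-type graph (`graph_builder`)

Within a subsystem, global MNN pairs (k = 10 for pre-gastrulation-scale
subsystems, 15 for organogenesis-scale) are classified by the type labels
of their endpoints, and every unordered node pair gets a normalized score
`100 · n_pairs / min(|A|, |B|)`. The normalizer is a convention (the
notion of "possible MNNs between two nodes" is not uniquely defined); the
raw pair count and a `min·k` normalization are emitted alongside for
sensitivity analysis. Pairs scoring above 1 become candidate edges. A
two-stage node-partition option supports scoring a core set of types first
and core-derivative edges second.

Orientation defaults to earlier-to-later median timepoint of the
MNN-participating cells; since inter-node MNN cells are temporally
coincident almost by definition, ties are broken by the node-wide median
timepoint. A curation table always overrides category and orientation;
spatial-continuity edges are forced bidirectional; manual edges can be
injected. The result materializes as a rooted `networkx.DiGraph`
(bidirectional edges stored both ways).

Dataset bridging co-embeds two tables (shared timepoints, intersected
genes) after per-dataset centering of the scaled matrix, computes *global*
MNN pairs and keeps the cross-dataset ones, scores cross-dataset node
pairs as above, and links reciprocal-best pairs above threshold, oriented
forward in time. Two guards reflect a real limitation of naive centering:
a cross-group (forced) neighbour search would fabricate matches even
between disjoint type sets, so the global mode is used; and because
centering cannot distinguish a batch offset from a composition difference,
candidates whose *uncorrected* centroid separation exceeds half the median
between-type centroid distance are rejected. The adjustment is deliberately
naive and pluggable — the contract is the interface, not the correction.

Progenitor mapping takes each derivative type with ≥ 500 cells, matches
its 500 earliest cells (by timepoint, ties by index) to the progenitor
pool by cross-group MNN (k = 10), and reports the normalized pair-count
distribution over pool territories; derivatives with < 50 pairs are
retried against the pool plus the early cells of already-mapped
derivatives, iteratively, and reported unmapped if they never reach the
pair floor.

## Transition phases and driver nomination (`transition_genes`)

A directed edge A→B is modeled as four disjoint groups: group 2 = A-cells
in inter-node MNN pairs, group 3 = B-cells in those pairs, groups 1 and 4
= within-type MNN partners of groups 2 and 3 (minus those groups). Small
groups grow to ≥ 200 cells by iteratively adding within-type MNN partners.
The mutual-kNN graph's transition-region component can stall below the
target; the group is then topped up with a seeded uniform sample of the
type's other MNN-participating cells. The fill is deliberately *random*
and restricted to MNN-participating cells: an embedding-guided fill
(e.g. nearest-to-centroid) selects cells by their position in expression
space, which is itself differential expression and produced strong false
calls on label-exchangeable null data, while unrestricted random fill
admits isolated low-MNN-degree cells whose expression profile differs
systematically from the MNN-derived contrast group.

Differential expression per phase contrast (1v2, 2v3, 3v4) is a two-sided
Wilcoxon rank-sum on log-normalized values with BH correction; genes
detected in < 10% of cells in both groups are dropped first, and
significance requires |lnFC| > 0.25 (natural-log fold change of average
de-logged expression, pseudocount 1) and adjusted p < 0.05. Nominated
genes are ranked per phase by adjusted p then |lnFC|; TFs are flagged from
the designated TF list, and genes nominated in exactly one of the early or
late phases carry an exclusivity flag.

Benchmark calibration: the power benchmark plants drivers with a per-cell
multiplier of ln(3.5) so that, at the measured transition-cell purity of
the internode groups (~40–65%), the *group-level* contrast the test
measures lands at ≈ 0.7–0.85 — the effect scale the recovery guarantee is
stated at. Driver genes are planted on well-expressed genes (top baseline
quartile outside the programs): a driver buried in dropout zeros has
intrinsically bounded rank-test power regardless of its fold change. The
null benchmark gives the child the parent's exact program, making the A/B
labels an exchangeable partition of one distribution.

## Temporal shift and growth (`temporal_shift`)

*Timepoint purity*: for one cell type, timepoints with ≥ 200 cells are
downsampled (seeded) to the median selected size m, the cells are
re-embedded (top 2,500 HVGs, PCA 30), and each cell's proportion of
k = round(log2 m) nearest neighbours from a different timepoint is
averaged per timepoint (k floored at 2). Eligibility requires ≥ 200 cells
at the final timepoint and at ≥ 5 earlier ones. A low value at one
timepoint means that timepoint's cells neighbour only each other — an
abrupt state shift. Under random labels with T equal groups of size m the
statistic has closed-form expectation (T−1)m/(Tm−1), which the suite
verifies by shuffling. "Different timepoint" is exact label inequality;
continuous times should be binned by the caller.

*Timepoint correlation*: Pearson r between each cell's timepoint and the
mean timepoint of its 10 nearest neighbours in the global embedding,
reported per group; high r indicates rapid synchronized change. Groups
with < k+1 cells or zero time variance report NaN.

*Growth*: ordinary least squares of log2 cell number on a cubic in
embryonic day (≥ 5 points required), with adjusted R². Doubling time at
day d is `24·2 / 2^p(d)` hours, where p is the derivative of the fitted
cubic (the log2-scale proliferation rate); non-positive rates give NaN.
With the published coefficients this predicts ~2.13×10⁵ cells and a ~6.3 h
doubling time at E8.5, stretching to ~32 h near birth.

## Axis and concordance analyses (`axis_analysis`)

Per requested PC, every feature (gene or covariate) gets a Pearson r
against the PC coordinates with a t-test p-value; a feature is significant
iff its r lies outside mean ± 1 SD of all r for that PC *and* its
BH-adjusted p < 0.05. Constant features are excluded. Sign-concordance
between two significant gene lists is a one-cell χ² goodness-of-fit of the
concordant count against a stated null fraction — 0.5 by default for a
two-list comparison (the null for matching signs between two lists is not
stated in the source analyses; 0.5 is the natural independence value), and
0.25 for the two-context replication check, where a gene replicates iff
its direction matches the discovery sign in *both* contexts.

## Problem sizes and tolerances

The benchmark sizes are fixed study conditions, chosen once: the lineage
benchmark uses 10 types over 9 half-day timepoints at 2,200 cells each
(~20k cells, bridge fraction 0.1, 3 seeds); the doublet benchmark 2 types
at 10k cells with 6% heterotypic doublets (3 seeds); the transition
benchmarks 10 power seeds and 20 null seeds at 8k and 2.5k cells; the
birth-series benchmark 2 types over 8 late-gestation timepoints at 700
cells each (5 seeds). Exact-search equivalence is asserted against O(n²)
scans up to n = 500. Numerical conventions (tie-breaks, PCA signs, the
min-max zero convention, NaN policies for undefined correlations and
doubling times) are documented above and asserted in the unit suite.

## Known limitations

* The normalized-MNN-score convention and the score > 1 candidacy rule are
  calibrated to each other; other normalizers shift the threshold's
  meaning (which is why alternatives are emitted, not silently swapped).
* Naive per-dataset centering cannot bridge datasets whose compositions
  differ strongly; the offset guard rejects such candidates rather than
  guessing.
* The four-phase stratification conditions on the same neighbour graph it
  tests, so its contrasts are selection-biased in principle; the null
  suite bounds this empirically for the shipped defaults but the bias
  grows with more aggressive expansion settings.
* Purity eligibility thresholds (200 cells, 5 pre-final timepoints) are
  inherited conventions for late-gestation data and are parameters, not
  laws.
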