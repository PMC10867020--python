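# Methods

`stemsig` re-implements, as a tested library, the computational procedures
used to contrast leukemic stem cells (LSCs, CD34+/CD38−) with leukemic
blasts (CD34+/CD38+) in t(8;21) RUNX1::ETO acute myeloid leukemia:
signature derivation from sorted bulk RNA-seq, signature-based
classification of single-cell clusters, differential chromatin
accessibility over peak unions, a motif enrichment score across peak sets,
and mass-cytometry population statistics. This note records the models,
parameter choices and numerical conventions, and what the synthetic-data
tests do and do not demonstrate.

## Bulk signatures

FPKM tables are upper-quartile normalized: each sample is scaled so its
75th percentile over genes with value > 0 equals the **geometric mean** of
all samples' upper quartiles (the method fixes only the quantile, not the
reference; the geometric mean is symmetric and scale-free), then
log2(x + 1) transformed for output.

LSC/blast signatures keep protein-coding genes with raw mean FPKM > 1 in
either sorted population and assign each gene to the population with the
higher normalized mean when the **linear ratio** of the UQ-scaled group
means exceeds `fc_threshold`. The ratio is taken on the linear scale
because a pseudocounted log scale would not absorb per-sample scaling
exactly. The default `fc_threshold` is 1.0 — any difference qualifies —
with 2.0 available; the any-difference rule is deliberately exposed rather
than silently tightened, but note it is sensitive to floating-point noise
at ratio exactly 1 (the test suite asserts the scaling-invariance property
at the 2-fold setting, where it is exact).

Subtype-specific genes (e.g. t(8;21)-specific) satisfy an
**all-versus-each** rule: the target group's mean must be at least `fold`
(default 2, inclusive ≥) times the mean of *every* other group
individually, not the pooled rest. Genes silent everywhere are excluded
(0 ≥ 2·0 is vacuous, not evidence).

## Single-cell pipeline

Cells live in an `AnnData`; raw UMIs in `layers["counts"]`, normalized
values in `X`. Processing order is QC → log-normalize → cell-cycle score →
regress/scale/cluster → contamination filter; the order of clustering
versus contamination filtering is a genuine choice and this package
clusters first so the filter operates on the same partition it reports.

* **QC**: keep cells with detected genes in [200, 5000] (inclusive at both
  bounds — the removal rule is "< 200 and > 5000") and mitochondrial UMI
  fraction ≤ 0.15.
* **Normalization**: x → ln(1 + 10⁴·x/total).
* **Cell-cycle scores** are binned-control module scores: mean normalized
  expression of the program genes minus the mean of control genes drawn
  per program gene from the same average-expression bin (equal-frequency
  bins, `n_bins=24`, `n_ctrl=100` draws per gene, union of draws, seeded
  generator). Phase: S if the S score is the larger positive score, G2M if
  the G2M score is, else G1; an exact positive tie goes to S (fixed
  arbitrary rule).
* **Clustering**: per-gene OLS on (intercept, S, G2M) replaces values by
  residuals; residuals are z-scaled, clipped at ±10 (genes whose residual
  variance is numerically zero are zeroed rather than amplified); full-SVD
  PCA (default 30 components); exact k-nearest-neighbour graph (k = 20)
  sharpened into a shared-nearest-neighbour graph by Jaccard overlap of
  neighbour sets (edges below 1/15 pruned); Leiden community detection
  with the RBConfiguration (modularity) objective at resolution 0.8,
  seeded. Cluster ids are renumbered by size descending for stability.
* **Markers**: two-sided Wilcoxon rank-sum of cluster versus rest on
  normalized values; average log2 fold change computed Seurat-style on
  de-logged means with pseudocount 1; keep |log2FC| ≥ 0.25 (or ≥ 0.5
  positively-enriched-only for the integrated LSC/blast list) and
  BH-adjusted p < 0.1. The rank-sum variant and pseudocount are exposed
  because toolkits differ on both.
* **Contamination filter**: clusters with fewer than 4 cells expressing
  the fusion-transcript gene (default *RUNX1T1*) are removed as healthy
  contamination.
* **Z-score heatmap**: per-cluster mean expression of a signature gene,
  z-scored across clusters with the sample standard deviation (ddof = 1,
  a convention that must be fixed — the tests pin it by hand computation);
  constant rows map to 0. Rows group by peak cluster and sort by peak Z.
* **Stand-ins**: anchor-based dataset integration is replaced by
  per-patient gene-mean centering (flagged in `uns`), and trajectory
  pseudotime by ordering clusters on ascending Blast-signature module
  score, i.e. most-LSC-like first. Both are deliberately simple,
  deterministic surrogates that preserve the LSC→blast axis; they are not
  the published integration/trajectory algorithms.

## Preranked GSEA and cluster classification

The enrichment statistic is the weighted Kolmogorov–Smirnov running sum
with weight exponent 1: walking the ranking (log2 fold changes sorted
descending, ties broken lexicographically by gene id), the sum gains
|score|/Σ|score over set genes| at set genes and loses 1/(N − N_hit)
elsewhere; ES is the extremum of largest magnitude. The null is
**gene-permutation**: `n_perm` (default 1000) uniform random same-size
sets from the ranking universe, seeded. NES = ES / mean |null ES of the
same sign|; nominal p = (1 + #{same-sign null ≥ |ES|}) / (1 + #same-sign
null), so p is never exactly 0 and lies in [1/(n_perm+1), 1]. No
multilevel p-refinement is attempted — the classification thresholds
(|NES| > 1, BH p < 0.05) need only this standard permutation NES.

Clusters are classified against a blast-minus-LSC ranking (positive score
= blast-high), each cluster's positively-enriched markers forming the gene
set; BH adjustment runs across clusters. NES > 1 with adjusted p < 0.05
reads Blast, NES < −1 LSC, anything else the intermediate "LSC/Blast".
The engine's correctness is pinned by an exhaustive step-by-step oracle on
all small rankings/subsets, and its null p-values are checked for
uniformity by a KS test (200 trials at n_perm = 1000).

Fold-change DE for counts tables (no-replicate setting): drop genes below
50 counts in every sample, CPM-normalize, call a gene up at a ≥ 2-fold
group-mean ratio; when replicates exist a configurable two-sample t-test
on log2(CPM+1) with BH p < 0.1 is additionally applied.

## Chromatin

Coordinates are BED 0-based half-open throughout; narrowPeak summit =
start + column-10 offset, midpoint when absent. Peak unions merge
overlapping **and bookended** intervals; the union summit comes from the
highest-scoring contributing peak (first encountered, i.e. leftmost, on
ties). Tag densities are per-bp means in a 400-bp window centred on the
union summit; CPM divides by the sample's genome-wide coverage total (not
the in-peak total), and fold calls use log2(CPM + 0.1) with a symmetric
≥ 2-fold rule. Ranked density matrices sort rows by descending A:B window
fold change with genomic order breaking ties, and apply the same order to
every sample. Average profiles define "peak height" as the central
(summit) bin of the site-averaged profile; per-sample scale factors bring
every height to the common mean, and the perturbation heatmap statistic is
the log2 ratio of normalized heights per site set. Sample similarity is
Spearman correlation over the union, displayed in complete-linkage
Euclidean clustering order. Peak→gene assignment prefers a promoter-capture
Hi-C fragment containing the summit (the loop identifies the target even
when another TSS is nearer); otherwise nearest TSS, ties to the
lexicographically smaller gene id.

## Motif enrichment

Motifs are position-probability matrices with per-motif log-odds
thresholds that must be supplied with the motif file (no silent default
cutoff). Probabilities are floored at 1e-3 before log-odds so legitimate
bases never score −∞; N bases do score −∞ and can never be part of a hit.
Scanning covers both strands of a 200-bp window centred on each summit.

The enrichment score S_ij = (n_ij/m_j) / (Σ_j n_ij / Σ_j m_j) compares
motif i's hit frequency in peak set j with its pooled frequency; n_ij
counts peaks containing ≥ 1 hit (per-site containment; a hit-multiplicity
mode exists for sensitivity analysis). The implementation evaluates
(n·Σm)/(m·Σn) so integer-valued fixtures give exact rational scores, and
the m-weighted mean of S_ij over sets is 1 to machine precision — an
algebraic identity asserted over random tables. Spacing profiles bin
partner-hit offsets around anchor hits; loess smoothing is display-only
and the raw bins are always emitted.

## CyTOF

Ion counts are log2(x+1) transformed; populations are compared per marker
by the difference of transformed means and a two-sided two-sample t-test
(pooled-variance Student by default, Welch selectable). Significance is
reported as display bands n.s./*/**/*** at cutpoints 1e-3, 1e-5, 1e-10,
inclusive on the small side (p = 1e-5 ⇒ **). Zero-variance markers with
equal means report p = 1. Both the transformed-scale means and the log2 of
raw-scale means are emitted because heatmaps of "log2 mean ion count" can
be read either way.

## Synthetic data: what it emulates, and what it does not

The generator is the package's study condition, not a tunable fixture.
Defaults: 2,000 genes; three populations of 500 cells (LSC, transition,
blast) with 100 planted markers per pole at log2 effect 2, the transition
carrying half of each pole's markers; cycle fractions 71/19/10 (LSC),
57/28/15 (transition), 43/37/20 (blast) — quiescent stem cells, cycling
blasts; 40-gene S and G2M programs at log2 effect 2; negative-binomial
counts (dispersion 0.4, mean library 6,000); a 10-gene MT- block whose
counts are Poisson so each cell's realized mitochondrial fraction tracks
its planted target (drawn from [0.01, 0.10]) tightly. The bulk panel
plants the same marker genes at 4-fold in their group, assigning planted
genes top-quartile baseline expression so upper-quartile scaling is
provably unaffected by the planting (also realistic: signature genes are
well-expressed). The peak landscape lays 2×100 non-overlapping 200-bp
peaks on a 140-kb random genome, inserts exactly round(rate·n) verbatim
motif instances at uniform offset and strand (rates 0.30/0.10 by default),
optionally mutates chance consensus occurrences so planted counts are
exact, and paints flat coverage at configured intensities over each 400-bp
summit window so window re-aggregation returns the intensity matrix
exactly. CyTOF tables are log-normal ion counts (base log2 means 6–10, so
the +1 pseudocount is negligible) with planted per-marker population
shifts.

Deliberately absent: read-level simulation, doublets, ambient RNA,
batch effects beyond a per-patient mean shift, GC-matched motif
backgrounds, and fragment-level coverage noise. Passing tests therefore
demonstrate algorithmic correctness and calibration under known truth —
not robustness to the full noise structure of droplet scRNA-seq or ATAC
libraries.

## Problem sizes and determinism

All analyses run at desk scale: 1,500 cells × 2,000 genes for the
classification harness (10 generator seeds), 200 permutation trials at
n_perm = 1000 for GSEA calibration, 1,000 random intervals for the
interval oracle. Every stochastic step takes an explicit integer seed and
a single `numpy.random.default_rng` stream per generator call; identical
seeds give bit-identical outputs, which the tests assert through file
serialization.

## Known limitations

* The Leiden partition is seeded and stable on well-separated data but is
  not guaranteed order-invariant on marginal graphs.
* The any-difference (`fc_threshold=1.0`) signature rule is exact-zero
  sensitive; use 2.0 when numerical noise between technically identical
  samples matters.
* The gene-permutation GSEA null is not fgsea's multilevel estimator;
  extremely small p-values saturate at 1/(n_perm+1).
* Per-patient centering and blast-score cluster ordering are stand-ins;
  conclusions about integration quality or trajectory topology are out of
  scope.
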