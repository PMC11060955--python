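# Methods

This note documents the statistical procedures implemented in `tempro`, the
defaults they use, what the synthetic generator does and does not emulate,
and the numerical choices made where the design was genuinely open. No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Study design and containers

The design is tissue × day × replicate: tissues default to tumor, draining
lymph node (LN), mesenteric lymph node (MLN), and spleen; days to
0, 3, 7, 10, 14, 21; replicates to 3. Day 0 represents the pre-implantation
state (cultured tumor cells / naive organs). The `ExpressionMatrix` couples a
gene × sample table of non-negative abundances with this design and a
provenance tag; all downstream stages consume it.

## Evidence tiers

Peptide-spectrum evidence is assumed pre-filtered to 1% peptide FDR by the
upstream search engine; the minimum peptide length is 7 residues. Tier
definitions:

* **tier 1** — any identified peptide.
* **tier 2** — (≥1 unique peptide AND ≥2 strict peptides) OR (≥3 strict
  peptides) OR (≥1 unique peptide with ion score ≥ 40), where *strict* means
  ion score ≥ 20 (boundary inclusive). A unique strict peptide counts toward
  both the unique and strict tallies; the alternative (excluding it from the
  strict count) would make a single peptide satisfy no clause below score 40,
  which contradicts the ≥40 clause's existence.
* **tier 3** — tier 2 plus detection (non-zero intensity) in at least two
  replicates of one (tissue, day) cell. With r ≠ 3 replicates the threshold
  stays at two (a literal reading of "two of three"), rather than scaling as
  ⌈2r/3⌉.

"Detected at sample level" is defined as non-zero intensity of any peptide of
a tier-2-qualifying gene; search engines rarely report a per-sample detection
flag, and non-zero intensity is the observable proxy. Tiers are nested by
construction and monotone in ion score (property-tested).

## Quantification

iBAQ = summed peptide intensity ÷ number of theoretical tryptic peptides.
The in-silico digest cleaves C-terminal to K/R, not before P, with peptide
length 7–30 and 0 missed cleavages by default (configurable); distinct
peptide sequences are counted. iFOT scales each sample column to a fixed
total of 10⁵, making columns comparable and scale-invariant to instrument
response. Isoform collapse sums protein-level values per gene: summation
preserves total signal and commutes with column normalization (tested).
Normalization is computed over the tier-2 quantified set and the matrix is
then subset to tier-3 for analysis, so totals reflect all confidently
quantified signal. Missing values stay 0 — no imputation; the pseudo-count
enters only at fold-change time. Replicate agreement is reported as Spearman
correlation over genes detected in both members of each within-cell pair.

## Differential expression

FC = (mean_a + 0.1)/(mean_b + 0.1). The pseudo value 0.1 buffers
low-expression genes and removes division by zero; on the iFOT scale (total
10⁵) it is far below typical expressed values. Significance: two-sided
equal-variance Student's t (Welch available by flag); identical zero-variance
groups return p = 1 (no evidence of difference) rather than NaN. BH
correction is applied within each contrast separately, matching per-day
comparisons. Calls: up iff FC ≥ threshold and adjusted p < α; down iff
FC ≤ 1/threshold; defaults threshold 2, α 0.05, with threshold 10 as the
stringent early-implantation variant — the two thresholds are independent
parameters, not a two-step filter. Kruskal–Wallis (tie-corrected, χ²
reference with k−1 df) serves multi-group comparisons; the all-identical
degenerate case returns (H = 0, p = 1) rather than propagating the rank
test's undefined statistic. A 2000-gene null simulation (same log-normal
law in both n = 3 groups) keeps the raw-p rejection rate at 0.05 inside the
99% binomial band (acceptance suite).

## Temporal clustering

Per-tissue profiles are replicate-averaged per day (the clustered object is
the temporal profile, not individual samples), log10(x + 0.1)-transformed,
and row-z-scored with the sample (n−1) standard deviation. Day 0 is excluded
by default: the pre-implantation state differs so profoundly from the
growing tumor that including it compresses all later dynamics. Fuzzy c-means
uses Euclidean distance, membership u_ij ∝ d_ij^(−2/(m−1)) normalized per
gene, and u^m-weighted centroid updates; the objective Σ u^m d² is monotone
non-increasing (asserted). Five seeded restarts are run and the lowest
objective kept; everything is deterministic given the seed. k defaults to 7
(the observed number of tumor patterns; no automatic selection is claimed).
When m is not fixed, it is estimated from the matrix dimensions with the
Schwämmle–Jensen heuristic

m = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406 ln N − 0.1134),

floored at 1.1. Phases are obtained by average-linkage clustering of samples
on 1 − Spearman ρ, cutting to the requested number of groups, and letting
replicates vote per day by majority.

## Co-expression modules

Correlations are Pearson on log10(x + 0.1) abundances (heavy-tailed iFOT
values would otherwise be dominated by a few genes). The network is
unsigned: adjacency = |cor|^β. β is the smallest candidate power whose
connectivity distribution reaches scale-free fit R² ≥ 0.8 (R² of
log-frequency vs log-connectivity over quantile bins, negative slope
required), else the argmax. Topological overlap:

TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij), TOM_ii = 1.

Modules come from average-linkage clustering of 1 − TOM with a simplified,
deterministic tree cut: all merge heights are scanned and the finest cut
maximizing the number of clusters of size ≥ min module size (default 50) is
kept. This replaces the full dynamic hybrid tree-cut — a deliberate
simplification trading its adaptive refinements for a testable, bounded
algorithm. Clusters below the size floor are absorbed into the module whose
eigengene they correlate with best (|r| ≥ 0.3, else unassigned/label 0), and
modules whose eigengenes have dissimilarity 1 − r below the merge height
(default 0.3) are merged iteratively. The eigengene is the first right
singular vector of the row-standardized module submatrix, unit norm,
sign-oriented to correlate positively with the module's mean profile; it is
verified against direct SVD and dominates all random unit-norm contrasts in
explained variance (tested).

Module–tissue association correlates eigengenes with 0/1 tissue indicators;
a module is tissue-associated when its top trait correlation is ≥ 0.6 (the
original assignment of modules to tissues was by inspection; the threshold
rule is an explicit, reproducible proxy). The tissue-specificity call is the
intersection rule: detected in exactly one tissue's tier-3 set (Venn-unique)
AND member of that tissue's associated module.

## Deconvolution

Mixture and signature columns are z-scored; the standardized mixture is fit
by non-negative least squares on the standardized signature columns. Because
a mixture's mean is the fraction-weighted mean of the signature columns, the
standardized-space coefficients equal f_j σ_j / σ_mix; dividing by each
column's σ before sum-to-one normalization therefore recovers the true
fractions exactly on noise-free data (to 1e−6 in tests). NNLS replaces the
original ν-SVR solver of signature-based deconvolution — a documented
deviation; the accuracy surface here is fraction recovery on synthetic
mixtures, not bit-equivalence with the published tool. Quantile
normalization is disabled. Significance is an empirical permutation p: the
fit statistic (Pearson r between reconstruction and mixture) is recomputed
under random gene-label permutations of the mixture,
p = (1 + #{null ≥ observed}) / (P + 1), default P = 1000, so the smallest
attainable p is 1/1001. Feeding proteomic mixtures to an RNA-derived
signature assumes RNA and protein rank cell types similarly; this caveat is
surfaced as a logged warning. Trajectories are mean fractions per cell type
per day.

## Enrichment and trajectories

Over-representation is the upper-tail hypergeometric test with the detected
proteome as background; gene sets are intersected with the background before
testing and BH-corrected across sets. Gene sets are user-supplied GMT — no
bundled ontology, keeping the package self-contained and offline. Function
trajectories z-score each member gene across all samples of one tissue and
average over members per sample; zero-variance genes are dropped with a
warning. Day-vs-day comparisons reuse the Student's t of the differential
stage, starred at <0.05/<0.01/<0.001/<0.0001. Functions are attached to
directions by enriching the union of up- (or down-) regulated proteins
pooled over the day-vs-baseline contrasts; the pooled-union reading was
chosen over per-day sets and is configurable upstream by passing single
contrasts.

## Drug-target prioritization

Per gene: Kruskal–Wallis across the four tissues' samples (all days and
replicates pooled — "average expression" is read as the tissue-wide mean),
BH over all tested genes; selected iff adjusted p < 0.05 and tumor mean
> 1.2 × each immune organ's mean individually (the strictest reading of
"exceeds 1.2 times that of the other three organs"; the pooled-mean reading
would admit genes high in one organ). Selection is monotone in both α and
the ratio (tested). Annotations come from a user-supplied TSV (gene,
druggable, status ∈ {approved, phase3, phase1_2, other}, semicolon-separated
categories) standing in for an external drug database snapshot; category
percentages are reported to one decimal (note 12/57 → 21.1%, which coarser
rounding prints as 21%).

## Synthetic generator

What it emulates: log-normal intensities spanning several orders of
magnitude (base log10 abundance N(1.0, 0.6), per-tissue offsets N(0, 0.3));
seven temporal archetypes in row-z units (decline, rise/dip/rise, mid-course
peaks, late rises, late jump, V-shape) added on the log scale with
configurable noise sd (default 0.2); tissue-unique proteins exactly zero
outside their tissue (default 5% per tissue, in the range of the per-tissue
unique proportions real datasets show); per-sample missing-at-random dropout
of peptide observations (default 0.2 — missingness mechanisms in label-free
data are unknown, so the simplest testable choice is used); planted evidence
tiers constructed so each tier rule is satisfiable or violated by design;
marker-structured signature matrices and Dirichlet mixtures with 5% relative
noise. Ground-truth differential calls are derived from the noiseless
expected values with the same pseudo-count rule, i.e. truth by construction.

What it does not emulate: correlated (abundance-dependent) missingness,
shared peptides across genes, ionization efficiency differences, batch
effects, co-regulation between temporal clusters, and RNA–protein
discordance in the deconvolution signatures. Passing recovery tests
therefore demonstrates algorithmic correctness under the stated model, not
robustness to every artifact of real LC-MS/MS data.

## Problem sizes and determinism

The test and acceptance workloads use desk-scale sizes chosen to exercise
every code path with comfortable margins: 1000 genes for tier recovery, 2000
genes for null calibration, 700 genes / 7 archetypes for clustering
recovery, two 60-gene blocks for module recovery, 100 mixtures for
deconvolution, and a 250-gene full-pipeline run executed twice for manifest
determinism. All randomness flows from a single root seed split per stage;
floats are serialized at 6 significant digits so output checksums are
stable across runs and platforms.

## Known limitations

* The simplified tree cut can split or lump differently from the dynamic
  hybrid algorithm near its decision boundaries; module counts on real data
  may differ.
* The scale-free fit is unstable on very small gene sets; `pick_soft_threshold`
  refuses fewer than 20 genes, and on toy data the chosen β can legitimately
  be 1.
* Tier-3 detection is intensity-based; an upstream pipeline exporting
  explicit identification flags per run could grade differently near zero
  intensities.
* The permutation p-value is granular at 1/(P+1); P = 1000 bounds it at
  ~0.001.
* Headline counts of the motivating study (e.g. 12,160 identified gene
  products or 110 database drug targets) depend on raw data, a search
  engine, and a specific database snapshot, and are out of scope here.
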