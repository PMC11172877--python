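# Methods

`bcplast` implements a survival-driven analysis pipeline for breast-cancer
expression cohorts: a per-gene consensus survival screen, prognostic
clustering, an EMT/stemness correlation score, nearest-centroid intrinsic
subtyping with plasticity statistics, and RNA-seq count normalization with
qPCR concordance. This note records the models, the parameters that
matter, and the design choices made where the procedure left room.

## The consensus survival screen

For each gene *g* with expression vector *x* and right-censored overall
survival (time in months from diagnosis, event = death observed), three
tests are computed on the same cohort:

1. **Maximally selected rank statistic.** Log-rank (Savage-type) scores
   `a_i = δ_i − Λ̂(t_i)` (Nelson–Aalen cumulative hazard) sum to zero; for
   every observed expression value μ with low-group proportion inside the
   quantile band (default 0.10–0.90) the low-group score sum is
   standardized by its permutation variance, and the cutpoint maximizing
   the absolute standardized statistic is selected. Samples with
   `x ≤ cutpoint` form the low group; ties in the maximum resolve to the
   smallest expression value. The selection-adjusted p-value uses the
   Brownian-bridge/improved-Bonferroni approximation

   `p ≈ 4φ(b)/b + φ(b)(b − 1/b)·log[ε₂(1−ε₁) / (ε₁(1−ε₂))]`

   for maximum b over the band (ε₁, ε₂), floored at the naive two-sided
   normal p at the chosen cutpoint (the adjustment can only make the test
   more conservative) and capped at 1. A seeded permutation alternative
   (`maxstat_pmethod="permutation"`) recomputes the maximum under score
   permutations; it is preferable for very small cohorts where the
   asymptotic approximation is rough.
2. **Univariate Cox regression** on the continuous expression value
   (configurably on the cutpoint dichotomy), fitted by Newton–Raphson on
   the partial likelihood with Efron tie handling (Breslow selectable);
   the Wald p comes from the asymptotic normal statistic. The covariate
   is standardized internally for numerical stability and the coefficient
   returned per unit of the original scale, so linear reparameterizations
   behave exactly. Monotone partial likelihood (separation) is detected
   (|standardized β| > 15) and flagged in the record rather than failing.
3. **Log-rank test** on the two groups induced by the maxstat cutpoint,
   via the standard observed-minus-expected sums with hypergeometric
   variances over distinct event times (the K-group generalization backs
   the clinical-covariate screen as well).

A gene is **selected** when all three p-values are below α = 0.05 — raw
p-values, no multiplicity correction, which is the original selection
rule; a Benjamini–Hochberg variant is available but off by default.
Direction is read from the hazard ratio: HR > 1 means higher expression
in the bad-survival group.

**Known limitation — false-discovery behaviour.** The three statistics
are computed from the same data and are strongly mutually correlated, so
the consensus null selection rate is roughly 1–2% at α = 0.05
(conservative relative to α, as the calibration tests verify), not the
product of the three nominal levels. When true survival genes are sparse
— e.g. tens of planted genes among thousands — those ~1.5% of null genes
dominate the selection and the false-discovery proportion is large
(around 0.6 in the planted-cohort benchmark the acceptance script
reproduces) even while sensitivity for the planted genes is high. Users
who need FDR control should switch on the BH option; the default
reproduces the original raw-p procedure faithfully.

## Prognostic clustering

Samples are clustered on a signature gene list with Euclidean distance
and complete linkage, cutting the tree at k = 2 (α/β). Genes are
median-centered across the cohort first (the red/green heatmap
convention); z-scoring or no scaling are selectable. Cluster naming
follows dendrogram leaf order, so output is deterministic and invariant
to input ordering. Kaplan–Meier curves per cluster use the product-limit
estimator (lifelines); the prognosis label is assigned from survival, not
from cluster numbering: the cluster with the shorter median survival
(an unreached median counts as infinite) is *bad*, ties broken by the
2-year survival probability and then by size (larger cluster = good).
The cluster comparison reuses the screen's log-rank test, so the two
module paths agree exactly on the same partition.

## Delta(r) stemness/EMT score

Each sample's expression over the stem/non-stem signature genes is
correlated (Pearson by default; Spearman selectable) with a non-stem/
epithelial template (NS/E) and a stem/mesenchymal template (CS/M);
`Delta(r) = r_CSM − r_NSE ∈ [−2, 2]`, negative = more epithelial.
Multi-column templates are summarized by the mean per-column correlation
(max selectable). Genes absent from a sample are dropped from both
templates symmetrically and counted. The published 15-gene template
values are not redistributable here, so templates are an explicit input;
`synthetic_templates()` provides a documented synthetic stand-in (15
genes, standardized Gaussian NS/E profile, exactly anti-correlated CS/M
profile) that reproduces the score's geometry (polar samples score ±2).
Cohort shifts are tested with a paired t-test for matched pre/post pairs
and Welch's t-test for unpaired arms; the reported mean difference is
after − before.

## Nearest-centroid subtyping and plasticity

A sample is assigned the class whose centroid profile it correlates with
best (Spearman by default, the canonical convention for PAM50-style
classifiers; Pearson selectable), requiring at least 30 shared genes.
Cohort classification median-centers each gene first (configurable off
for pre-centered data). Exact correlation ties break deterministically
to the class listed first, with a warning and zero margin. Canonical
PAM50 centroid values are an input file, not bundled; tests and
simulations use synthetic centroids. Plasticity between matched samples
is a K×K count matrix (rows = earlier/primary label, columns =
later/metastatic label) with overall retention (trace / pairs),
per-class retention (diagonal / row sum, undefined on empty rows),
switched counts and modal off-diagonal destination. Multi-metastasis
patients contribute one pair per metastasis, so the aggregate equals the
transition matrix of the flattened pair list exactly. The package ships
the published matched-cohort label tables (GSE10281, GSE32518, GSE32072,
GSE125989, GSE110590) as count matrices for these statistics.

## Count normalization and qPCR concordance

* **Median-of-ratios**: per-sample factor = median over all-nonzero
  genes of count / geometric-mean reference. Factors are defined up to a
  common scale; invariances therefore hold on factor ratios.
* **FPKM** = count / (length/10³) / (library/10⁶).
* **TMM**: against a reference sample (the one with upper-quartile count
  closest to the mean upper quartile), per-gene log2 ratios M and
  abundances A on genes nonzero in both; trim the extreme 30% of M and
  5% of A (both tails); factor = inverse-variance-weighted mean of the
  surviving M (delta-method weights 1/count + 1/count_ref),
  exponentiated; factors renormalized to multiply to 1. Because M here
  is the raw count log-ratio, the factors absorb both library depth and
  composition; trimming makes them robust to a minority of strongly
  shifted genes.
* **−ΔΔCt**: ΔCt = Ct_gene − Ct_housekeeping per sample; ΔΔCt subtracts
  the reference-group mean ΔCt per gene; the sign flip makes one unit ≈
  one doubling of expression, and the reference group scores 0 on
  average by construction.
* **Direction concordance** between two group-comparison tables counts
  shared genes whose after-minus-before mean differences have equal
  sign (zero matches only zero). Applied to the bundled published
  group-mean table, qPCR direction agrees with 12/17 genes under
  median-of-ratios normalization but only 4/17 (FPKM) and 5/17 (TMM) —
  the normalization scheme materially changes the apparent direction of
  treatment-induced expression changes.

## Synthetic cohorts

The generators emulate the study designs with known truth; all
randomness flows from one explicit seed.

* **Survival cohort**: two equal latent groups; exponential survival
  (Weibull shape 1 — the proportional-hazards model the screen assumes)
  with good-group hazard 0.01/month, bad-group hazard multiplied by the
  hazard ratio (at the default HR 4, bad-arm median ≈ 17 months — the
  scale of a poor-prognosis neoadjuvant TNBC arm). Expression is
  Gaussian on a log2-like scale (gene baselines N(7, 2), noise sd 1);
  planted genes shift by ±2 between groups (a clearly bimodal, 4-fold
  signature, mirroring a two-block prognostic heatmap), alternating
  direction. Censoring is independent uniform on [0, c] with c solved
  numerically so the expected censored fraction hits the target
  (default 0.3 — the follow-up pattern of the motivating cohort is
  unpublished, so this is an exposed assumption, not an estimate).
* **Paired shift**: with anti-correlated poles, Delta(r) = −2·r(sample,
  NS/E), so samples are constructed with exact target correlations: per
  pair a baseline Delta(r) ~ N(−0.3, 0.2) (mildly epithelial pre-therapy)
  and a post value raised by exactly the shift magnitude, then isotropic
  noise (default sd 0.05). At zero noise recovery is exact; small noise
  attenuates by < 1%.
* **Subtyped cohort**: timepoint-1 samples drawn around their class
  centroid (noise sd 0.3 against unit-variance centroids keeps
  single-sample accuracy ≈ 1 while leaving visible margins); timepoint-2
  class drawn from the row-stochastic switch matrix.
* **Counts**: gamma–Poisson with Var = μ + φμ², log-normal base means
  (median ≈ 55 counts), per-sample means scaled by the true size
  factors; φ = 0 degenerates to Poisson.

What the simulations do **not** model: batch effects, tumor purity,
microarray/RNA-seq platform differences, gene–gene correlation beyond
the planted group structure, and informative censoring. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under its own assumptions, not clinical validity on real
cohorts.

## Problem sizes and numerical choices

Recovery benchmarks use 100 samples × 2,000 genes (screen), 20
replicates of 60 × 150 (null calibration), 50 pairs (Delta(r)) and
4,000-gene two-sample count matrices (normalization); permutation
oracles use 4,000–10,000 permutations at n = 20. Newton iterations for
Cox stop at |step| < 1e−10 with step halving and a ±5 step cap;
correlation ties use a 1e−12 absolute tolerance; maxstat cutpoint ties
resolve to the smallest expression value; samples equal to the cutpoint
go to the low group. Degenerate inputs (constant vectors, all-censored
groups, empty matrices) raise typed errors rather than returning NaN,
except inside the whole-matrix screen where per-gene degeneracy is
recorded in the output row and the gene is never selected.
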