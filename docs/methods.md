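# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `comorbnet`. It states no result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Expression model and differential expression

Counts are assumed to be per-gene summaries of bulk RNA-seq for
case/control cohorts assembled from multiple studies, where study of
origin is the dominant nuisance variable (tissue, platform and cohort
effects are nested within study).

**QC.** Samples with less than 70% of reads aligned to the genome are
removed (`min_aligned`, default 70), then whole studies with fewer than 3
surviving cases, or no surviving control, are dropped (`min_cases`,
default 3). An empty result raises rather than propagating silently.

**Normalization.** Within-sample: log2 counts-per-million. Low-expression
filter: a gene is removed when its log2CPM is below 1 in *strictly more
than* 20% of the samples ("more than" read as a strict inequality; a gene
low in exactly 20% is kept). Between-sample: TMM scaling factors — the
doubly trimmed (30% on M, 5% on A), precision-weighted mean of gene-wise
log-ratios against the column whose upper quartile is closest to the mean
upper quartile, rescaled to geometric mean 1. The implementation
reproduces the reference R implementation (edgeR `calcNormFactors`) to
machine precision; the test suite cross-checks this via `Rscript`.

**Prior count.** The log2CPM prior is expressed on the CPM scale:
p_j = prior_count · L_j / 1e6 with L_j the TMM-effective library size and
prior_count = 0.5. Because p_j is proportional to L_j alone, the transform
is exactly invariant to rescaling any sample's counts (a pure depth change
moves the effective library size, not any logFC); at a balanced 1M-read
library it coincides with the usual 0.5 pseudo-count. The classic variant
that scales the prior by L_j / mean(L) is *not* depth-invariant — the
prior leaks through mean(L) and can shift low-count logFC by ~0.1 — which
is why this package departs from it. A residual, much smaller
non-invariance remains through the TMM precision weights (they scale by
1/s for the rescaled sample only); the property test bounds it at 5e-3.

**Linear model.** Per gene, unweighted least squares of log2CPM on an
intercept, condition (case = 1) and study indicator columns. Columns enter
in a fixed order (condition first, then study levels sorted
lexicographically) and aliased columns are dropped; a condition vector
expressible from the covariates (e.g. cases confined to one study and
controls to another) raises an explicit aliasing error. Precision weights
(voom-style) are not implemented: the model is the plain
limma-on-logCPM path, fit as homoskedastic least squares.

**Moderation.** Residual variances s² on d degrees of freedom are shrunk
to s̃² = (d0·s0² + d·s²)/(d0 + d). The prior (d0, s0²) is estimated by
moment matching on log s²: e_g = log s²_g − ψ(d/2) + log(d/2), then
trigamma(d0/2) = var(e) − trigamma(d/2) solved by Newton iteration, and
s0² = exp(mean(e) + ψ(d0/2) − log(d0/2)). When the observed spread of
log s² does not exceed the chi-square sampling spread, d0 = ∞ and every
gene is squeezed to s0². Genes with zero residual variance are excluded
from the hyperparameter fit (they carry no information about the prior)
but are squeezed like any other. Moderated t = logFC/(s̃·√v) on d0 + d df
(normal when d0 = ∞); two-sided p; Benjamini–Hochberg q-values; sDEG ⇔
q ≤ 0.05. The whole path matches limma `lmFit`/`eBayes` on the same
logCPM matrix to 1e-9 (cross-checked in the tests). The recovery test
plants s² ~ s0²·F(d, d0) at d0 = 4, s0² = 2 and requires the moment
estimates back within ±1 and ±10% on average.

**Batch removal (clustering only).** Per gene, log2CPM is regressed on
condition plus deviation-coded study indicators and only the fitted study
component is subtracted. The output feeds clustering and is never used
for differential expression.

## Similarity networks

An edge between phenotypes a and b is attempted when the union of their
sDEG sets, restricted to genes measured in both, has at least
`min_union = 10` genes (the degenerate-union cutoff is this package's
choice; skipped pairs are logged). The default edge statistic is
Spearman's rho over that union, with average-rank ties and the two-sided
t-approximation on n − 2 df; the alternative is cosine similarity with a
two-sided gene-permutation p (add-one smoothing). One BH correction is
applied jointly across all pairs tested in a network build — the
conservative reading of a flat FDR ≤ 0.05 edge criterion — and both signs
are kept. Phenotypes are ordered lexicographically so pair enumeration,
permutation streams and BH ranks are reproducible.

ICD9-level analysis relabels each disease by its 3-digit code, pooling
diseases that share a code (samples concatenated, studies preserved), and
reruns the identical pipeline.

## Epidemiological overlap

Both networks are restricted to their common node set. Recall = % of
epidemiological edges present in the molecular sign class; precision = %
of molecular sign-class edges present in the epidemiology. Significance:
the molecular sign-subnetwork is rewired by double-edge swaps (10× the
edge count per replicate, degenerate swaps rejected; a replicate whose
degree multiset differs from the original is an assertion failure), the
shared-edge count recomputed per replicate, and
p = (1 + #{replicates ≥ observed}) / (1 + n_perm), so p is never below
1/(n_perm + 1) and never exactly zero. Because the edge count of the sign
class is invariant under rewiring, the same exceedance drives recall and
precision. The overlap statistic is a small integer, so these add-one
p-values are deliberately conservative at ties; the calibration tests
therefore check uniformity on the randomized tie-broken version (exactly
uniform iff the rewiring ensemble is correct) and separately that the
reported p is never anti-conservative. Negative interactions are scored
against the same direct-comorbidity network as a sanity control and are
expected nonsignificant.

Two molecular networks are compared by the 2×2 Fisher exact test over all
common-node pairs (edge in A × edge in B); a zero margin flags the odds
ratio as 0/∞ rather than failing.

## Meta-patients

Stratification runs per disease on the batch-corrected log2CPM matrix
restricted to cases, with pairwise distance 1 − Spearman. PAM is a
deterministic BUILD + SWAP k-medoids: greedy seeding, then repeated
application of the single best improving (medoid, non-medoid) exchange,
ties always to the lowest index. Ward2 is agglomeration under the
ward.D2 convention (Lance–Williams on squared distances), validated
against a hand-executed recurrence. k scans 2..min(15, n − 1); a k is
admissible only if every cluster has ≥ `min_cluster_size = 3` cases (the
study-level 3-case minimum transferred to clusters); the admissible k
with the highest average silhouette wins, ties to the smaller k. Diseases
with fewer than 6 cases, or no admissible k, stay unstratified (one
meta-patient = the disease); a winning silhouette below 0.25 is flagged
low-confidence but kept.

Meta-patient differential expression reuses the disease-level normalized,
filtered matrix and refits the design on cluster cases vs *all* disease
controls. Re-normalizing per cluster would change TMM references and gene
universes across clusters; on the shared matrix the k = 1 stratification
is bit-identical to the disease profile and, in a single-study design,
the disease logFC equals the cluster-size-weighted mean of its
meta-patients' logFC exactly — both are enforced by tests.

The SSN is the same network build over diseases plus meta-patients; a
disease and its own meta-patients — and meta-patients of the same disease
— are never paired (they share samples and controls, so those
correlations are circular). The random-meta-patient null shuffles each
stratified disease's cases into clusters of the original size multiset,
refits meta-patient profiles, rebuilds the SSN, and counts positive and
negative meta-patient–disease edges (meta-patient–meta-patient edges are
excluded from the count); p is add-one as above.

A structural caveat the tests made explicit: when a disease has two
*equally sized* subtypes with exactly opposite effects, the edge-count
null has essentially no power — any random split with case imbalance m/n
retains (m/n)·effect signal, which over a large sDEG union remains
significant down to the smallest possible imbalance, so shuffled
replicates reproduce the observed counts. Detection-gain demonstrations
therefore use unequal subtype proportions (8 vs 26 cases), where every
shuffled cluster of either size leans toward the majority subtype's sign
and the minority subtype's positive links are genuinely invisible without
correct stratification.

## Enrichment

Preranked GSEA ranks genes by logFC descending (ties broken by gene id).
The ES is the classic weighted Kolmogorov–Smirnov running sum (weight
p = 1): hits add |score|^p normalized over the set's scores, misses
subtract 1/(N − N_hit), ES = signed extremum; maxima occur immediately
after hits and minima immediately before, so only those candidates are
scanned. The null is gene-label permutation (uniform random m-subsets of
ranked positions), NES = ES / mean(|same-sign null ES|), p sign-matched
with add-one smoothing, FDR by BH across sets (a deliberate, simpler
replacement for the original GSEA's sign-stratified FDR). Set-size bounds
default to 5..500.

Disease clustering binarizes NES to {+1, −1, 0} (significantly up, down,
neither at FDR ≤ 0.05), drops diseases with all-zero columns and applies
Ward2 on Euclidean distances. Edge profiling labels each positive
molecular edge EI (its ICD9 pair is in the epidemiological network) or
NEI, counts pathways significant in the same direction in both endpoints
per pathway category, and reports % of EIs/NEIs sharing ≥ 1 pathway, mean
shared counts, and their EI/NEI ratio.

## Synthetic cohorts

The generator emulates uniformly processed multi-study count data: gene
baseline means 2^N(4, 1.5); per-study, per-gene log-normal batch factors
(sd 0.5 on the log2 scale); per-sample log-normal depth factors (sd 0.3);
negative-binomial counts with dispersion 0.1; percent-aligned drawn as
60 + 40·Beta(2, 1), putting ~6% of samples below the 70% QC cutoff so the
filter has work to do. Disease signal is planted through gene modules: a
module has an intrinsic per-gene pattern (multipliers spread uniformly
over [1−h, 1+h], a fraction of genes sign-flipped), and a disease's cases
multiply module genes by 2^(effect · pattern). Sharing a module is what
makes two diseases' logFC vectors rank-correlated; the per-gene spread is
essential — under a uniform single-sign effect the shared signal has no
gene-level variation and Spearman cannot see it. Similarity-planting
helpers use h = 0.5 and a 50/50 up/down split; the split must be balanced,
because an asymmetric one (e.g. 70/30) systematically biases the rank
correlation between *any* two module-bearing diseases (the module block's
mean rank deviates from the grand mean) and plants edges the similarity
plan never declared. Subtype cases are allocated to subtypes exactly by
largest remainder (a binomial allocation would leak imbalance signal into
the pooled profile) and then ordered randomly. Planted truth (per-gene
effects, subtype labels, module memberships) is stored in a `truth` block
that no analysis stage reads.

The toy epidemiological network includes each planted positive pair with
probability `agreement` and adds uniform noise edges among unplanted ICD9
pairs, with a placeholder relative risk of 2. Enrichment fixtures emit
each module plus its directionally coherent `_up`/`_dn` subsets: the full
modules are bidirectional by construction (mean logFC ≈ 0), the
known low-power case for a running-sum enrichment score, whereas real
pathway collections are largely coherent.

What the generator does not emulate: gene–gene correlation beyond the
planted modules, GC/length biases, tissue-specific baselines, sample
covariates (age, sex, treatment), read-level artifacts, or realistic
pathway overlap structure. Passing tests therefore demonstrate the
statistical machinery — calibration, planted-structure recovery,
estimator consistency — not performance on real cohorts.

## Problem sizes and defaults

Calibration runs use 100 cohorts of 20 diseases × 2,000 genes
(10 cases/10 controls); planted-structure runs use 30 diseases × 2,000
genes with 120-gene modules at effect 2 and 20/20 samples; subtype runs
use 1,200 genes with a 200-gene module and 30–34 cases. Permutation
defaults: 1,000 for rewiring and meta-patient nulls in analyses (reduced
in some calibration tests, which only need the grid, and raised to 2,000
for GSEA in the pathway driver so the add-one floor clears BH across ~55
sets). All stages accept seeds and are deterministic given them.

## Known limitations

- Spearman edge p-values use the t-approximation; at unions barely above
  `min_union` the approximation is rough (the permutation-based cosine
  test is the robust alternative there).
- The edge-count nulls are conservative at ties by construction (add-one
  smoothing on integer statistics).
- PAM is a deterministic local optimum; the exhaustive-oracle tests cover
  small n only, and pathological distance matrices can in principle trap
  SWAP, as with any k-medoids implementation.
- GSEA FDR is plain BH across sets, not the original sign-stratified
  estimator; with many bidirectional sets this is conservative.
- Meta-patient profiles inherit the disease-level gene filter; genes
  expressed only within one subtype can be filtered out before
  stratification ever sees them.
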