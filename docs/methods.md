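# Methods

## Gene model and coordinates

All coordinates are GTF convention: 1-based, inclusive on both ends, and
all distances are computed on that scale. A gene's span is its 5′-most and
3′-most boundary over transcripts — taken from `gene` feature rows when
present (`gene_lines` policy, the default; GENCODE gene rows already encode
the union) or from the union of `transcript` rows (`transcript_union`).
TSS = start and TES = end on the plus strand, reflected on the minus
strand. Genes on unplaced scaffolds and chrM are retained; contig
filtering is a caller decision. `gene_type` strings are taken verbatim
from the annotation.

## Pair definitions

For a minus-strand gene M = [m1, m2] (TSS = m2) and a plus-strand gene
P = [p1, p2] (TSS = p1):

- **head-to-head (BG)**: m1 ≤ p1 and m2 ≤ p2 (divergent with a gap, or
  5′-overlapping), |m2 − p1| ≤ 1000, not nested. The orientation clause
  excludes convergent short-gene pairs whose *outer* TSSs happen to fall
  within 1 kb — without it those would slip through a pure distance rule.
- **tail-to-tail (CG1)**: the mirror image — p1 ≤ m1 and p2 ≤ m2,
  |m1 − p2| ≤ 1000, not nested.
- **tandem (CG2)**: same strand, non-overlapping, intergenic gap
  `start(downstream) − end(upstream)` in [1000, 10000]. Intervening genes
  are allowed (no adjacency constraint); overlapping same-strand genes
  yield no pair.

Distance cutoffs are inclusive by default; `inclusive=False` switches all
comparators to strict, exposing the "within vs less-than" reading as an
explicit flag. Nesting uses derived spans; identical spans count as nested
and are excluded. A gene may participate in several pairs (no
nearest-neighbor restriction). Control pairs containing any gene that
occurs in a BG pair are purged by gene membership. The stored
`distance_bp` is the class-defining distance (ΔTSS, ΔTES, or gap).

## Composition-matched random null

For each BG pair with gene-type combination (t₁, t₂), one random pair is
drawn with a uniform gene from each type pool, so each of the (default
100) sets reproduces the BG sets' size and type composition exactly.
Within a set genes are drawn without replacement (pairs of distinct
genes; flag `with_replacement` relaxes this); sets are independent, with
per-set seed = master seed + set index for bit-reproducibility.
Random pairs that coincide with a real pair are kept but counted.
Pools cover the whole genome by default (`exclude_bg_genes` removes
bidirectional genes). Matching is by type composition only — not length,
GC, or expression.

## Differential expression

Library-size normalization is trimmed mean of M-values (TMM): reference =
sample whose upper-quartile count fraction is closest to the mean; per
sample, a weighted mean of per-gene log2 ratios against the reference
after trimming 30% of M and 5% of A values on each side, weights the
inverse asymptotic (binomial) variance of M; factors are rescaled to zero
log-mean. The implementation reproduces edgeR's `calcNormFactors(method
="TMM")` to ~1e-7 (cross-checked in the test suite via Rscript).

The DE caller tests, per gene, H₀: |log₂ fold change| ≤ τ with
τ = log₂ 1.5 under a negative-binomial model:

- group means by the ratio estimator μ̂ₖ = (Σ yᵢ + ½) / Σ sᵢ over effective
  library sizes sᵢ = library size × TMM factor;
- per-gene dispersion by the method of moments on Pearson-type residuals,
  shrunk toward a binned-median mean–dispersion trend by an
  empirical-Bayes weighted average with 20 prior degrees of freedom
  (configurable);
- delta-method standard error of the log ratio, and the TREAT-style
  two-boundary tail p = P(Z > (|b|−τ)/se) + P(Z > (|b|+τ)/se);
- BH correction across tested genes; status `up` iff FDR ≤ 0.05 and fold
  change ≥ 1.5, `down` iff FDR ≤ 0.05 and fold change ≤ 0.67 (both
  boundaries inclusive, as printed conventions dictate — note 0.67 is the
  rounded reciprocal of 1.5).

Genes all-zero in both groups get p = 1. Fidelity to any particular GLM
implementation is intentionally not a goal; the caller is judged by its
operating characteristics (null call rate ≤ 7% at FDR 0.05 — in practice
≈ 0, because the threshold null is composite; sensitivity ≥ 0.8 at planted
|log₂FC| = 2 with 20 vs 20 samples).

The expressed-gene filter keeps genes with CPM ≥ 0.1 in at least
`n_normal` samples (samples from either group count). Dataset
eligibility — ≥ 200 tumor and ≥ 15 "Solid Tissue Normal" samples — is an
orchestration-level rule (`eligible_dataset`).

`ruv_lite` (off by default, k = 1 when enabled) estimates unwanted
variation as the sample coordinates of the first k singular directions of
the row-centered control-gene submatrix of log-CPM; the DE pass then
divides fitted control-factor effects out of the counts before testing.
Empirical controls default to the 1,000 least-significant genes of a
first pass.

## Promoter methylation

Promoter window: TSS − 2000 … TSS + 500 bp, strand-aware, clipped at 1;
probes are assigned to every gene whose window contains them
(multi-assignment expected; unknown chromosomes counted, not fatal).

Differential methylation operates on beta values directly with a
moderated two-sample t: pooled per-probe variances shrunk toward a scaled
inverse-chi-square prior whose df and scale are moment-matched on the log
variances (digamma/trigamma matching, Newton inversion of the trigamma);
t has df = residual + prior df; BH across probes; direction `hypo`
(tumor lower) / `hyper` requires adjusted p ≤ 0.05 and the matching sign.
The analogue tracks limma's eBayes p-values to ~5e-3 on the same matrix
(cross-checked via Rscript). No |Δβ| cutoff is imposed beyond
significance, and M-value testing is deliberately not used — thresholded
probe sets, not effect estimates, feed the downstream rule.

Methylation-correlation rule: basis `up_with_hypo` iff the gene is
up-regulated with ≥ 1 assigned hypo probe; `down_with_hyper`
symmetrically; else `none`. Pair combinations count both_hypo /
both_hyper / mixed / one / none; the headline statistic is the
both_hypo + both_hyper fraction. Pair-level CG1 methylation comparisons
are not computed by default (counts are too small to be meaningful);
datasets with < 3 normal methylation samples are excluded at the
orchestration level.

## Survival

Per endpoint (OS, DFI, PFI), patients with missing data are dropped per
endpoint. Gene screens fit a one-covariate Cox model on TMM-normalized
expression of tumor samples; pair screens a two-covariate model. The
reported p is the score test at β = 0 with the Efron tie correction —
the "logrank p-value" of R's `coxph` summary; the implementation matches
`coxph` `sctest` to 7 digits on tied data (frozen-oracle test).
Coefficients come from lifelines' `CoxPHFitter` (Efron). Degenerate
inputs (constant covariate, < 2 events, collinear pair) are skipped with
a recorded reason, never fitted.

Prognostic = score p ≤ 0.05. For prognostic pairs, samples are split at
each gene's median (strict ">" = high; ties go low; medians over tumor
samples) into four quadrant groups; the 4-group Cox model (dummy coding,
3-df score test) p ≤ 0.05 marks a *candidate* pair — a pair whose
expression-level combinations stratify survival. The headline comparison
restricts to pairs of two protein-coding genes. Survival p-values are
never multiplicity-adjusted (the report schema carries no adjusted
column): adjustment would empty the prognostic sets at typical cohort
sizes, and the screens are explicitly exploratory.

## Synthetic-data generator

`gen_annotation` plants head-to-head, tail-to-tail, tandem, nested, and
singleton structures with class-defining distances drawn from their
defining ranges (ΔTSS, ΔTES ~ U(0, 1000); gap ~ U(1000, 10000)), gene
lengths ~ U(2, 8) kb, and > 20 kb separation between structures — beyond
the 10 kb maximum pairing reach, so the planted truth is the *unique*
correct answer and recovery tests cannot be contaminated by accidental
pairs. Gene types are drawn from a four-type vocabulary (protein_coding
0.55, lincRNA 0.20, antisense 0.15, pseudogene 0.10), echoing the
dominant annotation categories of bidirectional genes.

`gen_counts` draws gamma-Poisson (NB) counts with lognormal baseline
means (median ≈ 50), lognormal depth factors (σ = 0.3), dispersion 0.1,
and a 30% all-zero stratum standing in for non-expressed genes. DE is
planted at rate `de_frac` with |log₂FC| = 2 by default; `pair_coupling`
is the probability that a planted head-to-head pair shares one DE draw
(same direction) instead of two independent ones — the co-regulation
knob. "Equal coupling" null experiments set it to 0, which makes BG genes
exchangeable with the random-null draws.

`gen_beta` places 2 probes per promoter plus 1 background probe per gene,
draws logit-normal betas, and shifts tumor betas by ±Δβ (default 0.25 in
the pipeline, 0.2 in the operating-characteristic checks) on planted
probes. Each planted DE gene receives a direction-matched promoter DMP
with probability `meth_coupling` (default 1); additional unlinked DMPs
are placed only on background probes and on promoters of non-DE genes, so
the set of genes satisfying the correlation rule is exactly the planted
one — the rule check is deterministic, and detector power is assessed
separately.

`gen_survival` draws exponential event times with hazard
λ₀·exp(Σ β_g z_g) over standardized expression of the planted prognostic
genes (λ₀ = 0.002/day), a log-normal frailty (σ = 0.5) shared across
OS/DFI/PFI with correlation 0.5 to couple endpoints, and independent
uniform censoring whose horizon is solved by bisection to hit the target
censoring fraction (0.3 default).

What the generators do *not* emulate: gene-length and GC effects on
counts, overdispersion trends, array probe-type chemistry, informative
censoring, and competing risks. Passing tests therefore demonstrate
correctness of the statistical machinery and the planted-truth recovery
logic, not robustness to every artifact of real cohort data.

## Problem sizes and numerical choices

The operating-characteristic checks use 2,000-gene null count matrices at
20 vs 20 (50–200 replicates), a 100-pair / 3,100-gene genome for the
enrichment comparisons (the background pool dwarfs the pair genes so the
composition-matched draw behaves as in a real genome), 200-replicate beta
nulls, and 500-patient / 2,000-gene survival screens — sizes at which the
asymptotic tests are well calibrated while a full run stays in the
tens of seconds. Ties in BH are handled by the step-up cumulative
minimum; the chi-square applies the Yates correction exactly for 2×2
tables (clipped at |O−E|, matching R); zero-variance probes and all-zero
genes are reported at p = 1 rather than NaN; all RNG flows through
`numpy.random.default_rng` with documented seed derivations
(per-set seed = master + index; pipeline sub-seeds = master·1009 + offset
mod 2³¹).

## Known limitations

- The genome-wide GENCODE v22 totals depend on undocumented choices of
  the original analysis (orientation rule, boundary inclusivity, contig
  set, TSS-sharing deduplication, CG2 adjacency); the defaults here are
  one documented combination, with flags to audit the alternatives.
- The DE, methylation, and survival callers are documented analogues of
  edgeR glmTreat, ChAMP, and RUVg pipelines, validated by operating
  characteristics and reference cross-checks, not bit-level replicas.
- Survival screens assume proportional hazards and use tumor samples
  only; quadrant groups use within-dataset medians, so group labels are
  not transferable across datasets.
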