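# bidipair

Discovery and pan-cancer co-regulation analysis of **bidirectional gene
pairs** — head-to-head gene arrangements in which the transcription start
sites (TSSs) of two genes on opposite strands lie within 1 kb of each
other, sharing a bidirectional promoter.

The package is aimed at computational biologists asking whether such pairs
behave as co-regulated units in tumors: are the two genes of a pair jointly
up- or down-regulated relative to matched normal tissue, jointly
methylation-correlated at their shared promoter, and jointly informative
about patient survival?

## What it does

1. **Pair discovery** (`annotation`, `pairs`). From a GENCODE-dialect GTF,
   each gene gets a span `[start, end]` from its 5′-most/3′-most transcript
   boundaries and a strand-resolved TSS/TES. Three pair classes are called:
   - **BG** — opposite strands, head-to-head, |ΔTSS| ≤ 1 kb;
   - **CG1** — opposite strands, tail-to-tail, |ΔTES| ≤ 1 kb (positional
     control);
   - **CG2** — same strand, intergenic gap in [1, 10] kb (tandem control).

   Nested genes (one span entirely inside another) are excluded, and
   control pairs containing any bidirectional gene are purged.
2. **Composition-matched random null** (`random_null`). 100 seeded sets of
   random pairs whose gene-type combination counts equal the BG pairs'
   exactly, drawn without replacement within a set.
3. **Differential expression** (`expression`). CPM ≥ 0.1 expressed-gene
   filter, TMM normalization, and a negative-binomial Wald test of
   H₀: |log₂FC| ≤ log₂ 1.5 with TREAT-style two-boundary tails and BH
   correction; genes with FDR ≤ 0.05 and fold change ≥ 1.5 (≤ 0.67) are
   up- (down-) regulated.
4. **Pair statistics** (`pair_stats`). Symmetric DE combination classes
   per pair (up_up, down_down, up_down, …), χ² comparisons between pair
   classes, one-sample t tests against the random-null mean ± SD, and
   recurrence histograms across datasets.
5. **Promoter methylation** (`methylation`). Probes mapped to promoter
   windows (TSS −2 kb … +500 bp, strand-aware), moderated-t differential
   methylation on beta values, and the correlation rule: an up-regulated
   gene with ≥ 1 promoter hypo-methylated probe (or down with hyper) is
   *methylation-correlated*.
6. **Survival** (`survival`). Cox proportional-hazards screens on
   TMM-normalized expression (1 covariate per gene, 2 per pair; Efron
   ties; score-test p ≡ the "logrank p" of R's `coxph`), median-split
   quadrant groups, and *candidate* prognostic pairs whose 4-group model
   is itself significant. No multiple-testing adjustment is applied to
   survival p-values, by design.
7. **Synthetic data** (`simulate`). Generators for annotation, counts,
   beta values, and survival with planted, recorded truth, so every stage
   is testable without any download.

## Worked example

Run the full pipeline on a synthetic study (30 planted BG, 20 CG1, 25 CG2
structures; two 20-tumor/20-normal count datasets; methylation; survival):

```bash
$ bidipair simulate --seed 5 --outdir study
n_bg    30
n_cg1   20
n_cg2   25
bg_upup_downdown_count  3
random_upup_downdown_mean       0.46
p_bg_vs_random  0.0004723366558845336
n_dmp   50
n_meth_correlated       1
n_prognostic_genes      11
n_prognostic_bg_pairs   0
n_candidate_bg_pairs    0
```

Reading the output: pair discovery recovered all 30/20/25 planted
structures. In the first dataset, 3 of the 30 BG pairs had both genes
called DE in the same direction, versus a mean of 0.46 across the 100
composition-matched random sets — the one-sample t test puts the
co-regulation excess at p ≈ 4.7×10⁻⁴. The methylation and survival stages
report 50 differential probes, 1 methylation-correlated gene, and 11
prognostic genes at this small sample size (prognostic *pairs* need larger
cohorts than 20 patients). All tables land in `study/`.

The same stages run on real inputs via `bidipair genes`, `bidipair pairs`,
`bidipair random`, `bidipair de`, `bidipair meth`, and `bidipair surv`;
see `--help` on each.

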