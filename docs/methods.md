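# Methods

## The association model

For each (variant, gene) pair on the same chromosome whose distance is
strictly below the cis window (1 Mbp by default; distance is measured
between the variant locus and the gene *interval*, 0 when they overlap —
a TSS-anchored mode is available via `build_cis_pairs(..., anchor="tss")`),
expression is regressed by ordinary least squares on the per-sample TE
presence dosage with an intercept, a sex indicator and K−1 population
indicators:

    y_s = b0 + beta * g_s + a * male_s + sum_k c_k * pop_{s,k} + e_s

* `g_s ∈ {0, 1, 2}` counts presence alleles. Records describing elements
  absent from the reference genome (`ALU_DEL`, `LINE1_DEL`, `SVA_DEL`) have
  their VCF ALT counts recoded to `2 − alt` at parse time, so `beta` has
  the same sign convention for insertion-coded and deletion-coded variants.
* Samples with a missing genotype are dropped for that pair only, never
  imputed.
* `beta` is tested with the usual t statistic on `n − p` residual degrees
  of freedom; Benjamini–Hochberg adjustment runs jointly over all *tested*
  pairs (pairs skipped as monomorphic, covariate-collinear or underpowered
  are excluded from the family and tallied); significance is `q ≤ 0.05`.
* Expression enters on its raw RPKM-like scale, matching how such scans
  are usually run on RPKM tables; `log2(x+1)` simulation/fitting is
  available behind the `log2_expression` switch for sensitivity checks.
* Zero-residual fits report `p = 0` with a `perfect_fit` flag instead of
  failing.

The scan is computed through the Frisch–Waugh–Lovell decomposition: the
covariate design is residualized out of the expression matrix and the
dosage matrix once (economy QR), after which each pair is a simple
regression on the projected vectors. This is algebraically identical to
per-pair OLS (asserted in tests against a closed-form normal-equations
oracle and against statsmodels) and makes 100 whole-scan randomizations
cheap. Pairs whose variant has missing dosages take a per-pair path with
the same algebra on the retained samples.

### Genotype-randomization validation

Each of R = 100 replicates independently permutes every variant's dosage
vector across samples (covariates and expression untouched — deliberately
breaking variant–variant LD, matching a per-genotype randomization), reruns
the full scan, and records the significant count. The observed count is
summarized as `z = (obs − mean)/sd` (sample sd, ddof = 1) and an empirical
p with a +1 pseudocount. When the replicate sd is 0, z is reported as
±inf/0 with a flag. Note that under a global null the observed scan is
exchangeable with the replicates, so a large |z| occurs essentially iff the
observed scan has any BH rejection — an event of probability ≈ the FDR
level per cohort. The 95% null-calibration target is therefore exactly at
its own expectation, and tests check it with a 3 Monte-Carlo-SE allowance.

## Enrichment randomization tests

* **Windows.** Chromosomes are tiled with 10 Mbp windows every 5 Mbp
  (starts at 0, step, 2·step, … while start < length); terminal windows are
  clipped and kept — Z scores stay comparable because the randomizations
  are counted over the identical window set. A feature increments every
  window it overlaps (half-open test). Randomizations place the same
  number of features with the same length multiset uniformly on the genome
  (chromosome chosen proportional to placeable length, start uniform and
  fully inside). `z > 3` calls enrichment; the empirical p (+1
  pseudocount, hence never 0 at finite R) is exported as −log10 for
  Manhattan-style plotting, with a BH q over windows per class.
* **Regulatory regions.** Observed statistic: percentage of a class's
  variants overlapping any regulatory interval (any-overlap, not
  bp-fraction — the simplest reading of an intersect-based protocol); the
  complementary non-regulatory percentage is reported alongside, with
  `z > 3` = enriched, `z < −3` = depleted.
* **Karyotype bands.** Feature counts per band divided by band length,
  ranked by density; multiple input lists (e.g. per-tissue eQTL sets) are
  ranked within group. The coordinate counted for an eQTL is its variant
  position, not the associated gene.

## Orientation and genomic context

Intra-genic variants (any gene overlap) are concordant when their strand
matches at least one overlapping gene's strand — the deterministic rule for
loci overlapping genes on both strands, which affects only a few percent of
variants in simulations. Strand-unknown variants are tallied separately.
Class-versus-class comparisons use the two-sided Fisher exact test (sum of
hypergeometric probabilities ≤ the observed table's probability).

Context labels use the precedence 3′UTR > 5′UTR > exon > intron, else
intergenic, so UTR localizations are never absorbed into a generic "exon"
call; a locus inside a gene span but outside annotated blocks counts as
intronic. Context enrichment of one set against another reports per-label
log2 percentage ratios with Fisher p-values.

## RNA-TEV matching

An insertion call supports a TEV iff same chromosome, same class,
point-to-point distance strictly below 50 bp, and the call's individual
carries the variant at DNA level (dosage ≥ 1) — DNA support is enforced
because a match is only meaningful in an individual genotyped as a carrier.
Each call is assigned to at most one TEV: the nearest eligible one, ties
broken toward the lower coordinate (collisions are not otherwise
addressed by the protocol). Matching is order-independent and the
class/distance/carrier constraints are asserted over all outputs in tests.

## Synthetic cohorts: what they emulate, and what they do not

Defaults mirror the targeted study design: 445 individuals from 5
populations, an Alu-dominated catalog (640/95/36 Alu/L1/SVA, a ~1:15
scale-down preserving the real 9605:1430:544 class imbalance), 15 % of
records deletion-coded, genotypes drawn under Hardy–Weinberg at each
variant's MAF. The MAF spectrum mixes a rare tail (45 % of variants below
5 %, down to the 3-carrier floor of 1.5/n) with a log-uniform common
component on [0.05, 0.5]. Expression is baseline exp(N(2, 0.7)) RPKM-like
units plus per-gene sex and population offsets (sd 0.5 each), planted
additive cis effects, and N(0, 1) noise, clipped at 0 (clipping affects
≈ 0.2 % of entries at these settings, so the generative model effectively
matches the fitted one). Planted effects (default β = 1.5 per allele) are
drawn among cis pairs whose variant is common (MAF ≥ 5 %), the regime
where single-cohort power is realistic; gene models carry
5′UTR–exon/intron–3′UTR substructure so context classification is
exercised; RNA calls are emitted per carrier with probability
`rna_tp_rate` at the variant position plus uniform jitter strictly inside
±`rna_jitter_bp` (< 50), plus configurable false calls.

Not emulated: linkage disequilibrium between variants, sequence content
(no FASTA/FASTQ), demographic history, expression-level covariance between
genes, and RNA-seq coverage effects on call sensitivity. Passing tests
therefore demonstrate correctness of the statistical machinery and
calibration under independence — not robustness to LD-induced correlation
among tests on real cohorts.

`make_scan_dataset` provides the clustered layout used for calibration
work: each gene in its own 3 Mbp slot with its variants within 0.5 Mbp, so
a 40-gene × 50-variant cohort yields exactly 2,000 cis pairs. Calibration
and power checks run at n = 200 samples, 2,000 pairs, 50 (FDR) / 20
(permutation) seed replicates — sizes chosen to give stable Monte-Carlo
estimates at interactive runtimes.

## Determinism and numerics

One global seed fans out to per-stage child seeds (SHA-256 of
`seed:stage`, truncated below 2³¹), so stages re-run in isolation
reproduce the pipeline run and two runs are byte-identical (no timestamps
in any output; manifests record config, stage seeds and input SHA-256
hashes). Collinearity is declared when the projected dosage variation
falls below 1e−10 of its raw scale; perfect fits below 1e−12 relative
residual. BH adjustment delegates to statsmodels and is property-tested
against the step-up definition; Fisher p-values delegate to scipy and are
oracle-tested against direct hypergeometric summation.

## Known limitations and notes

* The randomization Z uses the sample sd of the replicate counts
  (ddof = 1); with heavily zero-inflated counts the Z is a coarse summary
  and the empirical p is the more faithful quantity.
* Carrier counting interprets "present in ≥ 3 individuals" as ≥ 3 carriers
  (dosage ≥ 1), the reading consistent with 3/445 ⇒ 0.7 %.
* Published per-class tallies of this kind of catalog are not always
  internally consistent (e.g. an L1 extended-set count printed as 935 in a
  table against 937 in the text); the pipeline recomputes all counts from
  the data it is given and arbitrates nothing.
* Real-data scale results (tens of thousands of variants, hundreds of
  significant associations) require the original public downloads; the
  synthetic defaults are a faithful but scaled-down stand-in.
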