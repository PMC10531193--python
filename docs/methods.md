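# Methods

This note documents the models, default parameters, numerical choices, and
known limitations of each `regelex` component, and states what the
synthetic-data generators do and do not emulate.

## Synthetic data (`regelex.synthio`)

**Haplotype panel.** LD is generated by a founder-haplotype block model:
each block carries `n_founders_per_block` (default 4) random binary founder
haplotypes; each of the `2n` sampled haplotypes copies one founder and flips
each site independently with probability `mutation_rate` (default 0.01).
Blocks are mutually independent, SNPs are spaced 1 kb apart with 100 kb
between blocks, and SNPs that come out monomorphic are dropped and counted.
This gives controllable within-block r² and near-zero cross-block r², which
is all the downstream regressions need. It does **not** emulate recombination
gradients, allele-frequency spectra, demography, or realistic genome
coordinates; conclusions about those features cannot be drawn from these
fixtures.

**GWAS summary statistics.** True per-SNP effects are drawn
`β_j ~ N(0, Σ_C τ_C a_jC)` from binary annotations `a` and per-SNP
heritability coefficients `τ`; observed z-scores per block follow the
standard LD-aware model `z = √N·R·β + ε`, `ε ~ N(0, R)`, with `R` the
haplotype correlation matrix of the block (Cholesky with 1e-8 jitter for
near-duplicate SNPs). Effect/SE columns are reported on the
standardized-genotype scale (`se = 1/√N`). Generating z directly, rather
than via individual-level phenotypes, matches the regression model under
test exactly and keeps the experiments at desk scale.

**ATAC counts.** Negative-binomial (NB2, `var = μ + αμ²`) counts with
per-element baseline log2 means uniform on [3, 8], dispersion α = 0.1,
per-sample log-normal library factors (log2-scale SD 0.2), and a spiked
fraction (default 5%) of elements whose group-2 mean shifts by
`spike_log2fc` (default 2, i.e. 4-fold). Group sizes default to 10 vs 11,
mirroring a patient-versus-control cohort. Real ATAC features not emulated:
GC/fragment-length bias, peak-width variation, zero inflation from absent
elements.

**Allelic read counts.** Per (SNP, individual): heterozygote with
probability `het_rate`, Poisson depth, and at heterozygotes a beta-binomial
reference count with mean θ and overdispersion ρ; homozygotes read a single
allele. The published depth distributions of the emulated assays are not
stated anywhere usable, so the defaults (depth 30, het rate 0.5) are
placeholders chosen to look like a moderately sequenced bulk ATAC library,
not estimates of any particular study.

**Element atlas.** Disjoint 300-bp intervals on a synthetic chromosome.
Per (element, biosample), with probability `active_fraction` the Z-score is
`1.64 + Exp(1)`, otherwise standard normal truncated below 1.64, so the
realized active fraction is unbiased for the target by construction.

## Credible sets (`regelex.ldcred`)

Haplotype r² is `D²/(p_A(1−p_A)p_B(1−p_B))`, identical to the squared
Pearson correlation of the 0/1 haplotype indicators (tested to 1e-12). LD
expansion keeps partners with r² **strictly** greater than the cutoff
(default 0.7) within ±500 kb of the lead; the window is a config default —
typical GWAS locus practice — not an inference about any dataset.

Single-causal fine-mapping uses Wakefield's approximate Bayes factor
`ABF = √(se²/(se²+W))·exp(z²W/(2(se²+W)))` with prior effect variance
`W = 0.04` (prior SD 0.2 on the log-odds scale, the standard single-causal
choice), normalized across the locus (`PP_j = ABF_j/Σ_k ABF_k`, computed in
log space). The 95% credible set is the smallest PP-descending prefix
reaching coverage, ties broken by (PP desc, position asc), then members with
PP ≤ 1% are dropped. Calibration: with W matched to the simulation, the true
causal SNP lands in the 95% set in >99% of 500 simulated loci — above the
nominal 95% because the >1%-PP filter is applied after coverage and the
panel LD is exact. Variants found by both routes are tagged `both` to
support shared/unique accounting. Multi-causal search and conditional
analysis are out of scope.

## Atlas operations (`regelex.atlas`)

Activity calls use strict `Z > 1.64` in at least `min_datasets = 3` columns.
The "3 datasets" may come from any columns, including a single condition;
the source convention is ambiguous in that respect and this implementation
flags the choice here. All intervals are BED 0-based half-open; variant
tables are 1-based (VCF convention); the conversion lives in exactly one
function (`regelex.intervals.variant_pos_to_bed`). TCR-responsiveness per
lineage means BH q < 0.05 with the matching fold-change sign; CD4/CD8
unions, shared/unique sets, and the per-locus five-way classification
(`up_only`, `down_only`, `both`, `tcell_nonresponsive`,
`no_tcell_element`) follow by set algebra and are a partition by
construction.

## Differential accessibility (`regelex.diffacc`)

**Normalization.** For each sample, `M = log2(count+0.5) − mean log2` is
smoothed against the mean log2 abundance `A` with a loess fit (span 0.3,
config) and the fitted trend becomes the sample's per-element log2 offset;
offsets are centered per element. Working on raw log counts makes the
offsets absorb library size as well as abundance-dependent bias, so they are
the complete exposure term for the count model. Caveat inherited from all
trended normalization: the non-differential majority assumption must hold at
every abundance. If truly differential elements are the only occupants of an
abundance region (e.g. spiked elements pushed past the top of the baseline
range), the trend absorbs part of their signal; the calibration experiments
therefore place spikes interior to the abundance range.

**Testing.** Per element, group means are fitted by exact ML (damped Newton
on the log mean) on the NB2 model with offsets fixed; dispersion is profiled
per element on a log grid with the Cox–Reid adjustment (−½ log of the
per-group mean information), shrunk on the log scale toward the CR-adjusted
global value with prior weight equivalent to `shrink_df = 20` samples; the
group effect is a 1-df likelihood-ratio χ² with BH correction. Without the
CR adjustment the plain ML dispersion is biased low and the test runs
noticeably liberal; with it the measured null type-I error at 2,000 elements
and 10 vs 11 samples is ≈0.06. This machinery is deliberately simpler than
quasi-likelihood frameworks (csaw/edgeR): same analysis design, no QL
F-test, no abundance-dependent dispersion trend — and is documented as not
csaw-exact. Elements with zero total count are reported untested. Raw-p and
FDR cutoffs are both surfaced since downstream conventions differ (elements
at p < 0.01, genes at FDR < 10% style).

**Readouts.** The distribution-shift test is the two-sample KS with
asymptotic p (scipy). Motif enrichment is a per-motif Fisher exact test with
the plain cross-product odds ratio — no Haldane correction, so zero cells
report OR 0/∞ with the exact p intact — and BH across motifs scored in at
least one set. Chromatin states are rule-based: `active` if the
active-enhancer mark (H3K27ac) exceeds z 1.64, else `poised` if the priming
mark (H3K4me1) does, else `inactive`; the z cutoff is this package's
decision since the emulated state definitions are not published in reusable
form.

## Allele-specific accessibility (`regelex.allelic`)

Genotype from filtered read depths: `excluded` below 5 total reads, `het`
iff both alleles observed, else the matching homozygote. Reads are summed
across heterozygotes per SNP to (k, n). One **global** beta-binomial null
(μ, ρ) is fitted per dataset to all (k, n) pairs by bounded L-BFGS-B on the
exact likelihood (`α = μ(1−ρ)/ρ`, `β = (1−μ)(1−ρ)/ρ`; the ρ→0 limit is
evaluated as a binomial; method-of-moments start; μ pinned at a boundary is
flagged degenerate). Fitting on (k, n) pairs rather than on the fractions is
the likelihood-correct reading of "fit to the reference fractions" and is
noted as a possible divergence from other implementations.

Per-SNP significance is the two-sided exact minimum-likelihood p: the sum of
`P(k'|n, μ, ρ)` over all outcomes whose probability does not exceed the
observed one, with a 1+1e-7 multiplicative slack so floating-point ties on
the opposite tail are included. At ρ = 0 this reproduces an exact-rational
binomial enumeration to 1e-9 for all n ≤ 30. Nominal p < 0.05 is the
default reporting threshold, with BH q emitted alongside. Cross-dataset
concordance keeps SNPs significant in ≥ 2 datasets with identical direction
(sign of k/n − μ; exact ties never count).

Selection effect, documented not corrected: the same reads inform both the
heterozygote call and the test, so extreme imbalance can masquerade as
homozygosity and be excluded. Reference-bias filtering is assumed done
upstream of the input counts.

Power note: overdispersion scales with the depth of a single draw
(variance inflation `1+(n−1)ρ`), so one deeply sequenced heterozygote is
much less informative than the same total depth split across individuals.
At θ = 0.6 and ρ = 0.02 per heterozygote, pooling ~20 heterozygotes of
depth ~15 (pooled n ≈ 300 ≥ 150) yields ≥ 80% power at p < 0.05, whereas a
single pooled draw of depth 200 yields ~27%. The calibration experiments
use the multi-heterozygote design, which is how pooled counts arise in
practice.

## Stratified LD-score regression (`regelex.sldsc`)

LD scores: `ℓ(j,C) = Σ_k a_kC·r̃²_jk` over a ±window (default matched to the
simulated block span), including the self term, with the finite-panel
adjustment `r̃² = r² − (1−r²)/(n−2)` so cross-terms are approximately
unbiased. Regression: weighted least squares of χ² on `{N·ℓ(j,C)}` with a
free intercept (config flag to pin at 1); weights `1/(2(1+N·ℓθ̂)²)` iterated
once from an unweighted fit. Standard errors via delete-one block jackknife
over 20 contiguous SNP blocks (200 is genome-scale practice; 20 suits a
5,000-SNP chromosome). Enrichment `(h²_C/h²)/(M_C/M)` is jackknifed through
the delete values; the conditional p is the two-sided normal tail of
τ̂_C/SE. The all-SNPs annotation has enrichment exactly 1 by construction;
a non-positive total ĥ² makes every enrichment undefined and flags the
result degenerate. Collinear annotation columns raise with the offending
pair named.

Measured behaviour at the standard experiment (5,000 SNPs, N = 10,000, one
annotation with 50% of h² in 10% of SNPs, 50 replicates): mean estimated
enrichment ≈ 4.9 against truth 5, 95% jackknife CI coverage ≥ 90%, null
mean intercept ≈ 1.02. A single null replicate leaves ~0.08 MC spread on
the intercept, so unbiasedness is asserted on replicate means. This is a
pedagogical-scale reimplementation: one synthetic chromosome, no genome-wide
baseline annotation files, no MHC exclusion.

## Permutation enrichment (`regelex.permenrich`)

Observed statistic: risk SNPs inside elements. Null: draws of equal size
from the SNP universe without replacement, optionally within matched MAF
bins (both scheme and universe are recorded in the output). Empirical p uses
the add-one correction, bounded below by 1/(n_perm+1). For unmatched draws
the null is exactly hypergeometric; `exact_overlap_p` (scipy's log-space
survival function) is the oracle, and the permutation p agrees within 3 MC
SDs at 10⁵ permutations. SNP sets are permuted, not element sets; LD-aware
rotation schemes are out of scope.

## Integration (`regelex.integrate`)

PWMs carry per-position base probabilities with a 0.001 pseudocount
(renormalized); scores are log2-odds against background (uniform by
default), both-strand scanning takes the forward/reverse-complement max.
The allele delta with a fixed alignment reduces exactly to the single-column
ratio `log2(P(alt)/P(ref))`; negative means predicted reduced binding for
the alternative allele. Gene support: GWAS support iff any of the gene's
eQTL SNPs has GWAS p < 1e-6; ATAC support iff any eQTL SNP lies inside an
element with differential p < 0.01; expression tiers at FDR 10%/20%;
non-differential genes with both supports are flagged candidate risk genes.
eQTL significance is taken as given from the input table — no eQTL calling.
The same GWAS cutoff is used for the support flag everywhere; whether every
published display used exactly that cutoff is not verifiable, so it is a
single config value.

`run_pipeline` validates its config against the full schema before any
computation, derives every stage seed from the single top-level seed, and
writes outputs under a config-hashed directory so identical configs are
bit-identical reruns.

## Problem sizes

The test-suite and acceptance experiments use: 5,000-SNP panels (500
individuals) for LD-score regression; 500 loci for credible-set coverage;
2,000 elements (10 vs 11 samples) for differential calibration; 2,000
pooled SNPs for allelic calibration; 10⁵ permutations for the
permutation-vs-exact check; exhaustive enumeration elsewhere. These sizes
were chosen so each statistical property is measured with comfortable Monte
Carlo margin while the whole suite stays interactive.
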