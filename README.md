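# regelex

Dissecting noncoding GWAS risk loci through regulatory elements.

Most disease-associated variants found by genome-wide association studies
(GWAS) fall in noncoding DNA, where they are thought to act by perturbing
regulatory elements — enhancers and promoters whose activity is cell-type
specific. `regelex` implements, as a tested and reusable pipeline, the
computational arc of a regulatory-variant study of an immune-mediated
disease:

1. **Credible sets of candidate causal variants** per risk locus, by LD
   expansion (all variants with haplotype r² > 0.7 to the lead SNP) and by
   single-causal Bayesian fine-mapping (Wakefield approximate Bayes factors,
   95% credible sets, members kept at posterior probability > 1%).
2. **Element activity calling** from per-biosample Z-score matrices
   (active iff Z > 1.64 in ≥ 3 datasets), variant–element intersection with
   strict BED half-open semantics, and set algebra over T-cell-receptor
   (TCR) stimulation responses across CD4⁺/CD8⁺ lineages.
3. **Differential chromatin accessibility** on element × sample ATAC count
   matrices: loess MA-trend normalization followed by a negative-binomial
   likelihood-ratio test with Cox–Reid-adjusted, empirically shrunk
   dispersions; plus Kolmogorov–Smirnov distribution-shift tests, Fisher
   motif enrichment, and a chromatin-state (active/poised/inactive)
   transition caller.
4. **Allele-specific accessibility**: genotypes inferred from allele read
   depths (≥ 5 reads; heterozygote iff both alleles observed), reads pooled
   across heterozygotes per SNP, a *global* beta-binomial null
   (mean μ, overdispersion ρ) fitted by maximum likelihood, and per-SNP
   two-sided exact minimum-likelihood tests against it.
5. **Stratified LD-score regression** at desk scale: annotation-specific LD
   scores ℓ(j,C) = Σₖ a_kC·r̃²_jk, weighted regression of χ² on N·ℓ(j,C),
   block-jackknife standard errors, and heritability enrichment
   (h²_C/h²)/(M_C/M) with conditional coefficient tests.
6. **Permutation enrichment** of risk SNPs within element sets, with an
   exact hypergeometric oracle.
7. **Motif/eQTL integration**: PWM log-odds scoring, ref-vs-alt allele delta
   scores (negative = predicted decreased TF binding for the risk allele),
   and eQTL-based gene-support classification.

All of it runs end to end on synthetic data with known truth
(`regelex.synthio`): founder-haplotype LD blocks, LD-aware polygenic
summary statistics `z = √N·R·β + ε`, negative-binomial spiked count
matrices, and beta-binomial allelic read counts. Every simulator is a pure
function of its arguments including a mandatory seed.

Statistical cores follow the scikit-learn estimator convention
(`BetaBinomialModel`, `PartitionedLDScoreRegression`,
`NegativeBinomialDifferentialTest`: construct → `fit` → underscored fitted
attributes), with plain functions as thin wrappers.

## Worked example

Fit the allele-specific accessibility model on simulated counts:

```bash
regelex simulate allelic --n-snps 100 --n-individuals 10 --seed 4 --out-dir demo
regelex allelic --counts demo/allele_counts.tsv --out demo/allelic_results.tsv
```

prints

```
wrote 1000 allele count rows
fit mu=0.4938 rho=0.0120 on 100 SNPs; 7 significant at p<0.05
```

The fitted null says pooled heterozygote reference fractions center at
μ ≈ 0.49 with a small overdispersion (ρ ≈ 0.012, the residue of the
per-heterozygote ρ = 0.05 after pooling); this simulation contains no truly
imbalanced SNPs, and the 7/100 nominal hits match the expected 5% false
positive rate. Or run the whole pipeline from one config:

```python
from regelex import integrate
summary = integrate.run_pipeline({"seed": 1})
```

which returns (abridged)

```json
{
  "credible": {"lead": "rs13_19", "n_ld_set": 3, "n_finemap_set": 5, "n_shared": 3},
  "diff":     {"n_tested": 500, "n_called_q05": 32, "n_true_spiked": 25, "recall_q05": 1.0},
  "allelic":  {"n_snps_tested": 200, "mu_hat": 0.508, "rho_hat": 0.007, "n_significant_p05": 11},
  "ldsc":     {"intercept": 1.497, "enrichment_annot1": 2.77}
}
```

Reading it: the locus around the strongest association gets a 3-variant LD
set and a 5-variant fine-mapped credible set sharing 3 members; the
differential test recovers all 25 spiked elements at q < 0.05 while calling
32 in total; the LD-score numbers come from a deliberately tiny 500-SNP
demo, where a single replicate of the intercept and enrichment is noisy —
the calibrated behaviour at the full simulation scale (5,000 SNPs, 50
replicates) is what `scripts/acceptance.py` measures.

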