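# cohortsel

Detecting natural selection on trait-associated alleles across birth cohorts,
attributing it to reproductive pleiotropy, and converting the genetic change
into a predicted change in disease prevalence.

## The problem

When a common disease rises in prevalence over a few decades, one candidate
cause — alongside environment, diagnosis and demography — is that the
frequencies of its risk alleles are themselves changing under natural
selection. In a cross-sectional biobank, individuals born in different years
are sampled at the same calendar time, so allele-frequency differences across
*birth cohorts* proxy allele-frequency change through time. `cohortsel`
implements that inference chain for a myopia-style quantitative trait
(refractive error in diopters), and ships a synthetic-data generator with
planted ground truth so every stage is testable end to end.

The chain, stage by stage:

1. **Phenotype preparation.** Spherical equivalent SpE = sphere + cylinder/2,
   averaged over eyes; correction of the age-dependent hyperopic drift back to
   age 40 via a five-year aging schedule; myopia called as SpE40 < −0.5 D
   (strict); assignment to six five-year birth cohorts with sparse birth years
   excluded.
2. **Panel verification.** Covariate-adjusted OLS association of each
   candidate SNP with refractive error (age, sex, 10 principal components),
   QC (minor allele count < 5, missingness > 0.05, imputation info < 0.3),
   greedy LD pruning at R² > 0.8 keeping the stronger association,
   Benjamini–Hochberg FDR, and a risk-direction check.
3. **Selection scan.** Per-SNP regression of dosage/2 on birth year; the slope
   is the frequency change per year. Under a completely dominant advantageous
   allele (fitness 1+s for carriers), Δp ≈ p·s per generation, so
   s = slope × generation_time / p₀ with a 25-year generation. Direction
   counts among FDR-significant SNPs are tested with an exact two-tailed
   binomial sign test, and an empirical null is built from random control sets
   matched on allele frequency (±1%) and recombination rate (±0.05 cM/Mb).
4. **Lifespan screen.** A frequency trend can also arise if an allele shortens
   adult lifespan (older cohorts depleted of carriers at sampling). SNPs
   associated with either parent's lifespan (FDR < 0.05) are excluded before
   the sign tests.
5. **Pleiotropy attribution.** Associations of the selected SNPs with age at
   first live birth (AFB) and number of children ever born (NEB); consistency
   of each selection direction with the reproductive effect; Pearson
   correlation of s with effect sizes; χ² contrast against matched controls.
6. **Prevalence prediction.** Liability-threshold model with standardized
   genotypes w = (x − 2p)/√(2p(1−p)), liability y = Σ w·u + ε, residual
   variance var(Σw·u)·(1/h² − 1) at h² = 0.35; threshold calibrated so the
   reference cohort matches its observed prevalence, then reused across
   cohorts and averaged over 100 residual replicates. The prevalence increment
   is converted into excess cases (round(population × Δpoints/100)).

## Worked example

`examples/02_selection_scan.py` plants s = +0.06 and −0.06 at two of five SNPs
(six cohorts of 8,000) and scans the panel:

```
snp_id  slope_per_year  trend_q direction     p0         s
  snp0       0.0007631 7.84e-05         + 0.4029   0.04734
  snp1       -0.001615 2.69e-17         - 0.5047     -0.08
  snp2       4.273e-05   0.8031         0 0.3004  0.003556
  snp3       8.894e-05   0.7844         0 0.6012  0.003699
  snp4      -0.0001256   0.7844         0 0.5016 -0.006258

planted s: [0.06, -0.06, 0.0, 0.0, 0.0]
1 rising vs 1 falling among significant; sign-test p = 1
for the published tally (26 up, 6 down): p = 0.00054
```

Both planted signals are recovered with the right sign and magnitude (the
per-generation fitness advantage implied by the slope at the baseline
frequency); the three null SNPs stay non-significant. The other examples cover
scenario simulation (`01`), lifespan-confounding exclusion (`03`) and
liability-threshold prevalence prediction with excess-case arithmetic (`04`).

The same flow runs from the shell:

```sh
cohortsel simulate --scenario paper_like --seed 1 --out data/
cohortsel run --data data/ --out results/ --seed 1
cohortsel report --in results/
```

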