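"""Simulate a biobank-style cohort study and inspect the planted structure.

Builds the default paper-like scenario (213 candidate SNPs across six
five-year birth cohorts, 26 risk alleles under positive and 6 under negative
selection) at a reduced size, writes it to disk, and prints the observed
per-cohort myopia prevalence.
"""

from cohortsel import cohort_prevalence, generate_scenario, prepare_phenotypes

dataset, panel, pool, truth = generate_scenario("paper_like", seed=1,
                                                out_dir="scenario_demo",
                                                n_per_cohort=2000)
print(f"{dataset.n_individuals} individuals, {dataset.n_snps} SNPs, "
      f"{len(pool)} control-pool SNPs")
print(f"planted: {len(truth['selected_up'])} rising, "
      f"{len(truth['selected_down'])} falling risk alleles, "
      f"{len(truth['lifespan_set'])} with lifespan effects")

pheno, _ = prepare_phenotypes(dataset.phenotypes,
                              dataset.config.aging_schedule,
                              dataset.config.cohort_spec)
prev = cohort_prevalence(pheno["myopia"], pheno["cohort"])
print("\nobserved myopia prevalence (SpE at 40 < -0.5 D) by birth cohort:")
for _, row in prev.iterrows():
    lo, hi = row["ci_low"], row["ci_high"]
    print(f"  cohort {int(row['cohort']) + 1}: {row['prevalence']:.3f} "
          f"[{lo:.3f}, {hi:.3f}]  (n={int(row['n'])})")
print("\nThe first cohort sits at the calibrated 30.3% baseline; the rise "
      "across cohorts combines the environmental trend with the planted "
      "allele-frequency changes.")
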