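"""Predict per-cohort disease prevalence from genotypes alone.

Builds a liability-threshold model (standardized genotypes, h2 = 0.35),
calibrates the threshold so the first cohort matches a 30.3% reference
prevalence, and averages the predicted prevalence over residual replicates
while risk-allele frequencies rise across cohorts.  The resulting increment
is converted into excess cases in a population of 55.4 million.
"""

import numpy as np

from cohortsel import (LiabilityModel, excess_cases, fraction_of_increase,
                       predict_prevalence)

rng = np.random.default_rng(4)
m, n_per_cohort = 25, 8000
base = np.full(m, 0.4)

blocks, idx = [], []
for k in range(6):  # risk-allele frequency rises 1 point per cohort
    blocks.append(rng.binomial(2, base + 0.01 * k, (n_per_cohort, m)))
    idx.extend([k] * n_per_cohort)
dosages = np.vstack(blocks).astype(float)
cohort = np.array(idx)

model = LiabilityModel(u=np.full(m, 0.2), p=base + 0.025, h2=0.35,
                       n_replicates=100, seed=4)
pred = predict_prevalence(model, dosages, cohort, target_prevalence=0.303)
print(pred.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

rise = 100 * (pred["mean_prevalence"].iloc[-1] - pred["mean_prevalence"].iloc[0])
print(f"\ngenetic prevalence increment: {rise:.2f} points over six cohorts")
print(f"excess cases in a 55,429,643-person population: "
      f"{excess_cases(rise, 55_429_643):,}")
print(f"as published: 0.211 points -> {excess_cases(0.211, 55_429_643):,} cases, "
      f"{fraction_of_increase(0.211, 43.5 - 30.3):.1f}% of the overall rise")
print("\nThe first cohort reproduces the calibration target by construction; "
      "later cohorts rise only because their risk-allele dosages are higher.")
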