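"""Attribute selection signals to reproduction, excluding lifespan artifacts.

Runs the full pipeline on the lifespan-confounded scenario: SNPs whose
frequency trends are accompanied by parental-lifespan effects must be flagged
and excluded before the sign tests, because depletion of carriers in older
cohorts mimics positive selection.
"""

import numpy as np

from cohortsel import RunConfig, generate_scenario, run_pipeline

dataset, panel, pool, truth = generate_scenario("lifespan_confounded", seed=3,
                                                n_per_cohort=4000)
cfg = RunConfig(out_dir="lifespan_demo", n_control_sets=0, n_replicates=10,
                seed=3)
report = run_pipeline(cfg, dataset=dataset, panel=panel, pool=pool)

scan = report["stages"]["selection_scan"]
screen = report["stages"]["lifespan_screen"]
planted = set(panel["snp_id"].iloc[truth["lifespan_set"]])
flagged = set(screen["flagged_snps"])
jaccard = len(planted & flagged) / len(planted | flagged)

print(f"trend-significant SNPs before screen: {scan['n_significant']} "
      f"({scan['n_up']} up / {scan['n_down']} down)")
print(f"lifespan-flagged SNPs: {screen['n_flagged']} "
      f"(Jaccard vs planted truth: {jaccard:.2f})")
post = screen["post_exclusion"]
print(f"after exclusion: {post['n_up']} up / {post['n_down']} down "
      f"(sign-test p = {post['sign_test_p']:.3g})")
print("\nAll apparent selection in this scenario is a lifespan artifact, so "
      "the post-exclusion tally should be empty or tiny — the screen keeps "
      "survivorship bias out of the selection inference.")
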