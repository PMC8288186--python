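# Methods

## Model and inference chain

`cohortsel` treats a cross-sectional biobank as a stack of birth cohorts
sampled at one calendar time. The core estimand is the per-year change in a
risk allele's frequency across birth years, interpreted through a one-locus
selection model and propagated into a liability-threshold prediction of
disease prevalence.

**Selection model.** At a biallelic SNP with risk-allele frequency p and
q = 1 − p, the advantageous allele is assumed completely dominant: genotype
fitnesses are w(aa) = 1 and w(Aa) = w(AA) = 1 + s. One generation of selection
gives exactly

    Δp = p·s·q² / (1 + s − s·q²),

which for small s is Δp ≈ p·s. Both forms are implemented
(`simulate_allele_trajectory(model="exact_dominant" | "linearized")`); over a
span shorter than two generations the trajectory is virtually linear in
calendar year, which is why the scan uses a linear trend test and why
s = slope × generation_years / p₀ inverts the model. Generation time defaults
to 25 years. Dominance of the beneficial allele is an assumption, not an
estimate: deleterious alleles tend to be recessive, so their beneficial
counterparts act dominantly; under recessivity the same slope would imply a
larger s, so the reported s is conservative in that direction.

**Trend test.** Per-individual dosage/2 is regressed on birth year by OLS and
the slope tested against zero (two-tailed t). Regressing individual dosages
rather than the six cohort frequencies uses the full sample and makes the
slope estimand exactly the per-year frequency change; a cohort-level weighted
regression gives the same estimand and is available for comparison via
`cohort_allele_freq`. p₀ for s = Δp/p is the fitted frequency at the first
cohort's midpoint year (`p0_mode="fitted"`), which is less noisy than the raw
cohort-1 frequency; `p0_mode="raw"` switches to the latter.

**Sign test.** The up/down tally of FDR-significant trend SNPs is tested with
an exact binomial at null 0.5, two-tailed as min(1, 2 × smaller tail) — at a
symmetric null this equals summing all equally extreme outcomes.

**Matched controls.** The empirical null for "how many of a panel of k SNPs
show significant trends" is built by drawing random sets of k SNPs from a
genome-wide pool, matched per panel SNP on allele frequency (±1%) and
recombination rate (±0.05 cM/Mb), without replacement within a set and with
replacement across sets. Note that sets share pool SNPs, so per-set counts are
dependent; symmetry diagnostics are therefore computed over distinct sampled
SNPs.

**Association engine.** All trait associations (refractive error, parental
lifespans, AFB, NEB) use one OLS routine: phenotype on dosage + intercept +
covariates, classical standard errors, complete-case handling, two-tailed t
test. Degenerate designs (constant dosage, collinearity) are flagged, never
filled in. LD is computed as squared Pearson correlation of sample dosages
(pairwise-complete); pruning visits SNPs in order of increasing association
p (ties: smaller genomic position) and keeps a SNP only if its R² with every
kept SNP is ≤ 0.8 — equivalent to discarding the weaker member of each
high-LD pair, with a `random_removal` variant for robustness checks. FDR is
Benjamini–Hochberg, applied separately per trait family (refraction, each
parent's lifespan, AFB, NEB), since each family answers a separate question
and the source analyses report per-trait counts.

**Lifespan screen.** An allele that shortens adult lifespan depletes its
carriers from older cohorts, mimicking positive selection. SNPs whose
association with either parent's lifespan has q < 0.05 are excluded from the
panel before the sign tests and the prevalence model. The screen degrades
gracefully to one parent and warns when no lifespan data exist.

**Direction consistency.** A positively selected risk allele is *consistent*
if it significantly lowers AFB (earlier reproduction) or raises NEB (more
children); a negatively selected one, the reverse. Each FDR-significant
(SNP, trait) pair is one Bernoulli trial in an exact binomial at null 0.5.
Consistency is undefined where the trait association is not significant.

**Liability-threshold prediction.** Genotypes are standardized as
w = (x − 2p)/√(2p(1−p)) with a single whole-sample reference frequency p per
SNP, so cohort differences enter only through genotypes. Liability is
y = Σ w·u + ε with ε ~ N(0, var(Σw·u)·(1/h² − 1)); h² defaults to 0.35 (the
lower end of reported SNP heritability for refractive error — the
conservative choice). Per replicate, fresh residuals are drawn, the threshold
y₀ is set to the empirical (1 − target)-quantile of the reference cohort's
scores, and the same y₀ is applied to all cohorts; means and standard errors
over 100 replicates are reported. u comes from the refractive-error betas:
u = −β·√(2p(1−p)) (risk-positive liability scale). Missing genotypes are
imputed to 2p (w = 0), neutral under the standardization. Calibrating within
each replicate makes the reference cohort reproduce its target exactly in
expectation; predictions are invariant to rescaling all u by a positive
constant, since the residual variance rescales with the genetic variance.

## Synthetic-data generator

The generator instantiates exactly the structure the analysis assumes, so
recovery tests are parameter-recovery tests, not approximations:

- Birth years uniform within six five-year cohorts (1940–1969 by default);
  genotypes Binomial(2, p_birthyear) with p from the planted trajectory
  (Hardy–Weinberg at every birth year, no LD between SNPs).
- Liability = Σ dosage·u + Gaussian residual with variance
  var(genetic)·(1/h² − 1); SpE at 40 is liability plus an affine calibration
  constant chosen so the first cohort's myopia prevalence equals a configured
  target (30.3% by default). u is on the diopter scale with risk alleles
  negative, so higher liability maps to more negative SpE as required.
- Observed refraction = SpE40 + cumulative aging shift to exam age (five-year
  bands, prorated linearly; default +0.10 D per 5 years from 40 to 75 — the
  schedule is an input, not a constant) + an optional environmental trend per
  birth year. The observed value is split into per-eye sphere and cylinder
  with mean-centered between-eye scatter, so `spherical_equivalent` and
  `correct_to_age40` recover SpE40 exactly.
- NEB = round(max(0, baseline + Σ dosage·β + noise)); AFB is defined only when
  NEB ≥ 1; parental lifespans are baseline + Σ dosage·β + N(0, 10²) years.
  Exam ages are 40–70 (exam years 2006–2010, floored at age 40).
- Sex ~ Bernoulli(0.5); 10 PC columns are standard Gaussian noise (they carry
  no structure; their inclusion tests covariate plumbing, not stratification).
- The control pool draws each pool SNP's frequency and recombination rate near
  a round-robin-assigned panel SNP, guaranteeing admissible matches at the
  ±1% / ±0.05 cM/Mb tolerances when the pool is ~10× the panel.

Scenarios: `paper_like` (213 SNPs; 26 positively and 6 negatively selected,
reproductive effects aligned with selection on a subset, a few
lifespan-affected SNPs, and an environmental trend sized to dominate a
~13-point prevalence rise), `all_null` (no selection, no effects), and
`lifespan_confounded` (all frequency trends carry strong negative lifespan
effects that the screen must remove).

Planted selection coefficients in `paper_like` are drawn from |s| ∈
[0.05, 0.10] with baseline frequencies in [0.30, 0.70]. Real single-SNP
coefficients of ~0.006–0.02 would need hundreds of thousands of individuals
per replicate to reach per-SNP trend significance; the scenario instead fixes
the power at its default size (10,000 per cohort) so that the *count
structure* (26 up vs 6 down after FDR) is the recoverable truth. The
acceptance check for coefficient magnitude uses s = 0.02 at 50,000 per cohort,
where the estimator is adequately powered.

What the generator does **not** emulate — and therefore what passing tests do
not establish about real data: linkage disequilibrium between panel SNPs
(pairwise-correlated duplicates exist only to exercise the pruner), population
structure and genotyping batch effects (PCs are pure noise), ascertainment and
participation bias, phenotype measurement error beyond the between-eye
scatter, non-Gaussian trait residuals, and any causal path from the trait to
reproduction (myopia and reproductive traits are linked only through shared
SNPs, so group contrasts between myopic and non-myopic individuals are weak in
synthetic data even when per-SNP pleiotropy is strong).

## Numerical choices and degenerate inputs

- Frequencies are clipped to [1e−6, 1 − 1e−6] in trajectories and p₀.
- OLS uses explicit normal equations with a condition-number guard (>1e12
  flags the fit degenerate) — hundreds of SNP fits per stage make per-fit
  model objects wasteful; statsmodels cross-checks the routine in tests.
- BH q-values ignore NaN p-values (degenerate tests) and do not count them as
  tests performed.
- Two-sample comparisons default to Welch's t-test; a pooled-variance switch
  exists. The χ² contrast uses no continuity correction (the printed
  headline value requires Pearson's statistic; Yates would give ≈9.6).
- Threshold calibration uses `np.quantile` (linear interpolation); realized
  prevalence matches the target within 1/n.
- Tie-break in LD pruning: smaller genomic coordinate, then input order.
- Missing genotypes: complete-case in association and trend tests (per SNP);
  imputed to the HWE mean only inside the liability predictor.
- Cohort assignment drops birth years with fewer than 100 individuals and
  anything outside the configured cohorts, with per-reason counts logged;
  an all-excluded result aborts the run rather than continuing silently.
- RNG: a single master seed spawns independent per-stage streams
  (`numpy.random.SeedSequence`), so reports are byte-identical across reruns
  up to the echoed output path.

## Known limitations

- The selection model cannot distinguish direct selection from selection on
  linked variants; s is "direct or linked" by construction.
- The per-SNP s estimator is noisy at realistic effect sizes and biobank
  scale; the robust signals are the direction counts and their sign tests.
- The lifespan screen conditions on parental lifespan as a proxy for carrier
  survivorship; it cannot catch survivorship effects not expressed in
  parental lifespans.
- Statistical pleiotropy (shared association) is not biological pleiotropy;
  the attribution stage makes no causal claim.
- The liability model is purely additive; dominance and epistasis in the
  genetic architecture, and GREML estimation of h², are out of scope (h² is
  an input).

## Problem sizes used in the shipped checks

Unit and property tests run at hundreds to a few thousand individuals per
cohort; the acceptance-style checks use six cohorts of 50,000 for
selection-coefficient recovery (50 replicates), 1,000 null SNPs at 2,000 per
cohort for size calibration, 10,000 per cohort at 25 replicates for the
liability model, and ~8,300 per cohort for the lifespan-confounded scenario.
These sizes were chosen so each estimator operates in its adequately powered
regime.
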