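"""Synthetic biobank-style cohort data with planted selection and pleiotropy.

The generator instantiates the statistical structure the downstream analysis
assumes: diploid biallelic SNPs whose risk-allele frequencies drift linearly
with birth year under selection, a heritable liability phenotype expressed as
spherical equivalent (SpE, diopters), reproductive traits (age at first live
birth, number of children ever born) and parental lifespans with per-SNP
allelic effects, and an age-dependent hyperopic shift of the observed
refraction.  Every planted parameter is recorded in the SNP panel's truth
fields so each analysis stage can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "CohortDataset",
    "make_panel",
    "default_aging_schedule",
    "simulate_allele_trajectory",
    "simulate_individuals",
    "simulate_control_pool",
]

#: default six five-year birth cohorts
DEFAULT_COHORTS: tuple[tuple[int, int], ...] = (
    (1940, 1944),
    (1945, 1949),
    (1950, 1954),
    (1955, 1959),
    (1960, 1964),
    (1965, 1969),
)

PHENOTYPE_COLUMNS = [
    "iid", "birth_year", "sex", "exam_age",
    "sphere_R", "cyl_R", "sphere_L", "cyl_L",
    "afb", "neb", "mother_lifespan", "father_lifespan",
] + [f"pc{i}" for i in range(1, 11)]

_FREQ_EPS = 1e-6


def default_aging_schedule(delta_per_5y: float = 0.10, age_max: int = 75) -> pd.DataFrame:
    """Uniform hyperopic aging schedule: SpE shifts by ``delta_per_5y`` diopters
    per five-year age band from age 40 to ``age_max``.

    The longitudinal five-year changes this table stands in for are an input to
    the pipeline, not a constant of it; any table with columns
    ``age_start, age_end, delta_spe_per_5y`` may be supplied instead.
    """
    starts = np.arange(40, age_max, 5)
    return pd.DataFrame({
        "age_start": starts,
        "age_end": starts + 5,
        "delta_spe_per_5y": delta_per_5y,
    })


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort study.

    Effects are per risk allele: ``u_true`` on SpE in diopters (risk alleles
    carry negative values — more myopic), ``beta_afb`` in years, ``beta_neb``
    in children, ``beta_lifespan`` in years of parental lifespan.  ``s_true``
    is the selection coefficient per generation (``generation_years`` years).
    """

    n_per_cohort: int = 1000
    cohort_spec: tuple[tuple[int, int], ...] = DEFAULT_COHORTS
    baseline_freqs: np.ndarray = field(default_factory=lambda: np.array([0.5]))
    s_true: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    u_true: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    beta_afb: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    beta_neb: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    beta_lifespan: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    h2: float = 0.35
    target_prevalence_cohort1: float = 0.303
    env_trend_per_year: float = 0.0
    aging_schedule: pd.DataFrame = field(default_factory=default_aging_schedule)
    generation_years: float = 25.0
    trajectory_model: str = "linearized"
    missing_rate: float = 0.0
    pool_size: int = 0
    seed: int = 0

    # trait baselines (population means for carriers of zero risk alleles)
    afb_mean: float = 25.0
    afb_sd: float = 4.5
    neb_mean: float = 2.0
    neb_sd: float = 1.2
    mother_lifespan_mean: float = 78.0
    father_lifespan_mean: float = 72.0
    lifespan_sd: float = 10.0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.baseline_freqs, dtype=float)
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise ValueError("baseline_freqs must lie strictly in (0, 1)")
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must lie in (0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        spans = sorted(self.cohort_spec)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 >= b0:
                raise ValueError("cohort spans must be non-overlapping and ordered")
        n = len(freqs)
        for name in ("s_true", "u_true", "beta_afb", "beta_neb", "beta_lifespan"):
            if len(np.asarray(getattr(self, name))) != n:
                raise ValueError(f"{name} must have one entry per SNP")

    @property
    def n_snps(self) -> int:
        return len(np.asarray(self.baseline_freqs))

    @property
    def first_year(self) -> int:
        return self.cohort_spec[0][0]

    @property
    def last_year(self) -> int:
        return self.cohort_spec[-1][1]


def make_panel(config: SimulationConfig,
               recomb_rates: np.ndarray | None = None,
               prefix: str = "snp") -> pd.DataFrame:
    """Build the SNP metadata panel (with truth columns) for a configuration.

    One SNP per entry of ``config.baseline_freqs``; positions are spread over
    22 autosomes in input order, recombination rates default to a deterministic
    spread over 0.1-2.1 cM/Mb.
    """
    m = config.n_snps
    idx = np.arange(m)
    if recomb_rates is None:
        recomb_rates = 0.1 + 2.0 * ((idx * 0.37) % 1.0)
    alleles = np.array(["A", "C", "G", "T"])
    return pd.DataFrame({
        "snp_id": [f"{prefix}{i:05d}" for i in idx],
        "chrom": (idx % 22 + 1).astype(str),
        "pos": 10_000 + idx * 5_000,
        "risk_allele": alleles[idx % 4],
        "other_allele": alleles[(idx + 1) % 4],
        "baseline_freq": np.asarray(config.baseline_freqs, dtype=float),
        "recomb_rate": np.asarray(recomb_rates, dtype=float),
        "s_true": np.asarray(config.s_true, dtype=float),
        "u_true": np.asarray(config.u_true, dtype=float),
        "beta_afb": np.asarray(config.beta_afb, dtype=float),
        "beta_neb": np.asarray(config.beta_neb, dtype=float),
        "beta_lifespan": np.asarray(config.beta_lifespan, dtype=float),
    })


def simulate_allele_trajectory(p0: float, s: float, years: int,
                               model: str = "linearized",
                               generation_years: float = 25.0) -> np.ndarray:
    """Deterministic risk-allele frequency at years 0..``years`` under selection.

    ``linearized`` applies the weak-selection increment dp = p*s per generation
    (p taken at the start of each generation) with linear interpolation between
    generation boundaries, so the trajectory is piecewise linear in calendar
    year — effectively exactly linear over a span shorter than two generations.
    ``exact_dominant`` instead applies the one-generation recurrence for a
    completely dominant allele A with genotype fitnesses w(aa)=1,
    w(Aa)=w(AA)=1+s:

        dp = p*s*q**2 / (1 + s - s*q**2),   q = 1 - p,

    again interpolated linearly within a generation.  Output is clipped to
    [1e-6, 1 - 1e-6].
    """
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must lie strictly in (0, 1), got {p0}")
    if model not in ("linearized", "exact_dominant"):
        raise ValueError(f"unknown trajectory model: {model!r}")
    n_gen = int(np.ceil(years / generation_years)) + 1
    knots = [p0]
    p = p0
    for _ in range(n_gen):
        q = 1.0 - p
        if model == "linearized":
            dp = p * s
        else:
            dp = p * s * q * q / (1.0 + s - s * q * q)
        p = float(np.clip(p + dp, _FREQ_EPS, 1.0 - _FREQ_EPS))
        knots.append(p)
    t = np.arange(years + 1, dtype=float)
    traj = np.interp(t / generation_years, np.arange(n_gen + 1, dtype=float), knots)
    return np.clip(traj, _FREQ_EPS, 1.0 - _FREQ_EPS)


@dataclass
class CohortDataset:
    """In-memory synthetic cohort study.

    ``genotypes`` holds risk-allele dosages (0/1/2) as float with NaN marking
    missing calls, individuals in rows in the same order as ``phenotypes``.
    """

    genotypes: np.ndarray
    phenotypes: pd.DataFrame
    snp_ids: list[str]
    config: SimulationConfig | None = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def cohort_masks(self, cohort_spec=None) -> list[np.ndarray]:
        spec = cohort_spec or (self.config.cohort_spec if self.config else DEFAULT_COHORTS)
        by = self.phenotypes["birth_year"].to_numpy()
        return [(by >= a) & (by <= b) for a, b in spec]


def _genotypes_at_years(freqs_by_year: np.ndarray, year_index: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg dosages: Binomial(2, p_birthyear) per individual."""
    p = freqs_by_year[year_index]
    return rng.binomial(2, p).astype(float)


def simulate_individuals(panel: pd.DataFrame, config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> CohortDataset:
    """Draw one cohort study under the configured generative model.

    Per individual: birth year uniform within the cohort, genotypes
    Binomial(2, p) at the birth-year frequency from the planted trajectory,
    liability = sum(dosage * u_true) + N(0, var_g*(1/h2 - 1)), SpE at 40
    obtained from liability by an affine shift calibrated so the first
    cohort's myopia prevalence (SpE < -0.5 D) equals the configured target,
    observed refraction = SpE40 + cumulative aging shift to exam age +
    environmental trend; reproductive and lifespan traits are baseline +
    sum(dosage * beta) + Gaussian noise (NEB floored at 0 and rounded, AFB
    defined only when NEB >= 1).
    """
    if config.h2 <= 0:
        raise ValueError("h2 must be positive (residual variance undefined at 0)")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    cohorts = config.cohort_spec
    n = config.n_per_cohort * len(cohorts)
    birth_year = np.concatenate([
        rng.integers(a, b + 1, size=config.n_per_cohort) for a, b in cohorts
    ])
    first_year = config.first_year
    year_index = birth_year - first_year
    n_years = config.last_year - first_year

    m = len(panel)
    geno = np.empty((n, m), dtype=float)
    for j in range(m):
        traj = simulate_allele_trajectory(
            panel["baseline_freq"].iloc[j], panel["s_true"].iloc[j], n_years,
            model=config.trajectory_model, generation_years=config.generation_years)
        geno[:, j] = _genotypes_at_years(traj, year_index, rng)

    u = panel["u_true"].to_numpy(dtype=float)
    genetic = geno @ u
    var_g = float(np.var(genetic))
    resid_sd = np.sqrt(var_g * (1.0 / config.h2 - 1.0)) if var_g > 0 else 1.0
    liability = genetic + rng.normal(0.0, resid_sd, size=n)

    env = config.env_trend_per_year * (birth_year - first_year)
    # affine calibration: choose intercept c so that cohort-1 prevalence of
    # SpE40 = liability + env + c below -0.5 D equals the target
    in_c1 = (birth_year >= cohorts[0][0]) & (birth_year <= cohorts[0][1])
    ref_scores = liability[in_c1] + env[in_c1]
    c = -0.5 - np.quantile(ref_scores, config.target_prevalence_cohort1)
    spe40 = liability + env + c

    exam_age = np.array([
        rng.integers(max(40, 2006 - by), 2010 - by + 1) for by in birth_year
    ], dtype=float)
    aging_shift = cumulative_aging_shift(exam_age, config.aging_schedule)
    spe_observed = spe40 + aging_shift

    # split observed SpE into sphere + cylinder/2 per eye with small
    # between-eye scatter so the SpE formula has real work to do
    cyl = -np.abs(rng.normal(0.3, 0.2, size=(n, 2)))
    eye_dev = rng.normal(0.0, 0.1, size=(n, 2))
    eye_dev -= eye_dev.mean(axis=1, keepdims=True)
    sphere = spe_observed[:, None] + eye_dev - cyl / 2.0

    beta_neb = panel["beta_neb"].to_numpy(dtype=float)
    beta_afb = panel["beta_afb"].to_numpy(dtype=float)
    beta_ls = panel["beta_lifespan"].to_numpy(dtype=float)
    neb_raw = config.neb_mean + geno @ beta_neb + rng.normal(0, config.neb_sd, n)
    neb = np.maximum(0, np.round(neb_raw))
    afb = config.afb_mean + geno @ beta_afb + rng.normal(0, config.afb_sd, n)
    afb[neb < 1] = np.nan
    mother = config.mother_lifespan_mean + geno @ beta_ls + rng.normal(0, config.lifespan_sd, n)
    father = config.father_lifespan_mean + geno @ beta_ls + rng.normal(0, config.lifespan_sd, n)

    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = np.nan

    pcs = rng.standard_normal((n, 10))
    pheno = pd.DataFrame({
        "iid": [f"id{i:07d}" for i in range(n)],
        "birth_year": birth_year,
        "sex": rng.integers(0, 2, size=n),
        "exam_age": exam_age,
        "sphere_R": sphere[:, 0], "cyl_R": cyl[:, 0],
        "sphere_L": sphere[:, 1], "cyl_L": cyl[:, 1],
        "afb": afb, "neb": neb,
        "mother_lifespan": mother, "father_lifespan": father,
        **{f"pc{i + 1}": pcs[:, i] for i in range(10)},
    })
    return CohortDataset(genotypes=geno, phenotypes=pheno,
                         snp_ids=list(panel["snp_id"]), config=config)


def cumulative_aging_shift(exam_age: np.ndarray, schedule: pd.DataFrame) -> np.ndarray:
    """Accumulated hyperopic SpE shift from age 40 to each exam age, prorating
    linearly inside five-year bands."""
    exam_age = np.asarray(exam_age, dtype=float)
    shift = np.zeros_like(exam_age)
    for _, band in schedule.iterrows():
        lo, hi = float(band["age_start"]), float(band["age_end"])
        overlap = np.clip(np.minimum(exam_age, hi) - np.maximum(40.0, lo), 0.0, None)
        shift += band["delta_spe_per_5y"] * overlap / (hi - lo)
    return shift


def simulate_control_pool(config: SimulationConfig, panel: pd.DataFrame,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Genome-wide pool of neutral SNPs for matched resampling.

    Pool SNPs carry s_true=0 and no trait effects; their allele frequencies and
    recombination rates are drawn in the neighbourhood of panel values
    (stratified round-robin over panel SNPs) so that every panel SNP has
    admissible matches within the +-1% frequency and +-0.05 cM/Mb tolerances.
    """
    if config.pool_size <= 0:
        raise ValueError("config.pool_size must be positive to build a control pool")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    m = len(panel)
    anchor = np.arange(config.pool_size) % m
    freq = panel["baseline_freq"].to_numpy()[anchor] + rng.uniform(-0.008, 0.008, config.pool_size)
    freq = np.clip(freq, 0.01, 0.99)
    rr = panel["recomb_rate"].to_numpy()[anchor] + rng.uniform(-0.04, 0.04, config.pool_size)
    rr = np.clip(rr, 0.0, None)
    zeros = np.zeros(config.pool_size)
    idx = np.arange(config.pool_size)
    alleles = np.array(["A", "C", "G", "T"])
    return pd.DataFrame({
        "snp_id": [f"ctrl{i:06d}" for i in idx],
        "chrom": (idx % 22 + 1).astype(str),
        "pos": 500_000_000 + idx * 5_000,
        "risk_allele": alleles[idx % 4],
        "other_allele": alleles[(idx + 1) % 4],
        "baseline_freq": freq,
        "recomb_rate": rr,
        "s_true": zeros,
        "u_true": zeros,
        "beta_afb": zeros,
        "beta_neb": zeros,
        "beta_lifespan": zeros,
    })


def simulate_pool_dosages(pool: pd.DataFrame, birth_year: np.ndarray,
                          rng: np.random.Generator,
                          snp_indices: np.ndarray | None = None) -> np.ndarray:
    """Neutral HWE dosages (constant frequency over birth years) for pool SNPs.

    Used by the matched-control scan, which needs genotypes only for the
    sampled control SNPs rather than the whole pool.
    """
    freqs = pool["baseline_freq"].to_numpy(dtype=float)
    if snp_indices is not None:
        freqs = freqs[snp_indices]
    n = len(birth_year)
    return rng.binomial(2, freqs[None, :], size=(n, len(freqs))).astype(float)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=int(seed))
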