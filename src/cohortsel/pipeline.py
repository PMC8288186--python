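"""End-to-end pipeline: simulate -> prepare -> verify -> scan -> attribute ->
predict, as a configured, seeded, logged run with a machine-readable report.

Stage order mirrors the analysis design: phenotype preparation; verification
of the candidate SNP panel against refractive error (QC, LD pruning, FDR,
risk-direction check); birth-cohort allele-frequency trend scan with matched
control sets; lifespan screen and exclusion; sign tests; reproductive
pleiotropy tests; liability-threshold prevalence prediction and excess-case
arithmetic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as dataio
from .assoc import (QCThresholds, assoc_scan, bh_fdr, ld_prune,
                    orient_risk_allele, qc_filter)
from .liability import (LiabilityModel, excess_cases, fraction_of_increase,
                        liability_effects_from_betas, predict_prevalence)
from .phenotypes import cohort_prevalence, prepare_phenotypes
from .pleiotropy import (direction_consistency, group_t_test, lifespan_screen,
                         reproductive_assoc, s_effect_correlation)
from .selection import (binomial_sign_test, control_scan,
                        sample_matched_controls, scan_panel)
from .simulate import (DEFAULT_COHORTS, CohortDataset, SimulationConfig,
                       make_panel, simulate_control_pool, simulate_individuals)

logger = logging.getLogger("cohortsel")

SCENARIOS = ("paper_like", "all_null", "lifespan_confounded")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, constants and paths for one pipeline run."""

    data_dir: str = "."
    out_dir: str = "out"
    fdr_level: float = 0.05
    r2_threshold: float = 0.8
    qc: QCThresholds = field(default_factory=QCThresholds)
    myopia_cutoff: float = -0.5
    min_cohort_n: int = 100
    generation_years: float = 25.0
    h2: float = 0.35
    n_control_sets: int = 100
    n_replicates: int = 100
    population: int = 55_429_643
    cohort_spec: tuple[tuple[int, int], ...] = DEFAULT_COHORTS
    use_corrected_spe: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (("fdr_level", 0, 1), ("r2_threshold", 0, 1),
                             ("h2", 0, 1)):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name} must lie in ({lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw:
            raw["qc"] = QCThresholds(**raw["qc"])
        if "cohort_spec" in raw:
            raw["cohort_spec"] = tuple(tuple(c) for c in raw["cohort_spec"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# scenario generation
# ---------------------------------------------------------------------------

def _paper_like_config(n_per_cohort: int, seed: int) -> tuple[SimulationConfig, dict]:
    """213-SNP panel: 26 positively and 6 negatively selected SNPs, reproductive
    effects aligned with the selection direction on a subset, a handful of
    lifespan-affected SNPs, and an environmental trend that dominates the
    prevalence rise."""
    rng = np.random.default_rng(seed)
    m = 213
    s = np.zeros(m)
    sel_idx = rng.choice(m, size=32, replace=False)
    up_idx, down_idx = sel_idx[:26], sel_idx[26:]
    s[up_idx] = rng.uniform(0.05, 0.10, 26)
    s[down_idx] = -rng.uniform(0.05, 0.10, 6)
    freqs = rng.uniform(0.05, 0.95, m)
    freqs[sel_idx] = rng.uniform(0.30, 0.70, 32)  # power for the trend test

    u = -rng.uniform(0.02, 0.08, m)  # every panel SNP is trait-associated

    beta_afb = np.zeros(m)
    beta_neb = np.zeros(m)
    # positively selected: 8 lower AFB, 5 raise NEB (one SNP overlaps)
    afb_up = up_idx[:8]
    neb_up = up_idx[7:12]
    beta_afb[afb_up] = -(1.5 * s[afb_up] + rng.uniform(0.05, 0.15, 8))
    beta_neb[neb_up] = 0.6 * s[neb_up] + rng.uniform(0.02, 0.05, 5)
    # negatively selected: 1 raises AFB, 2 lower NEB
    beta_afb[down_idx[:1]] = -1.5 * s[down_idx[:1]] + 0.1
    beta_neb[down_idx[1:3]] = 0.6 * s[down_idx[1:3]] - 0.03

    beta_ls = np.zeros(m)
    ls_idx = np.concatenate([up_idx[24:26], sel_idx[-1:],
                             np.setdiff1d(np.arange(m), sel_idx)[:4]])
    beta_ls[ls_idx] = -rng.uniform(0.8, 1.5, len(ls_idx))

    # environmental trend sized to dominate the prevalence rise (~13 points
    # over the cohort span), expressed in liability-sd units per year
    var_g = float(np.sum(2 * freqs * (1 - freqs) * u ** 2))
    liab_sd = np.sqrt(var_g / 0.35)
    env = -0.0121 * liab_sd

    cfg = SimulationConfig(
        n_per_cohort=n_per_cohort, baseline_freqs=freqs, s_true=s, u_true=u,
        beta_afb=beta_afb, beta_neb=beta_neb, beta_lifespan=beta_ls,
        h2=0.35, target_prevalence_cohort1=0.303, env_trend_per_year=env,
        missing_rate=0.01, pool_size=10 * m, seed=seed)
    truth = {"selected_up": up_idx.tolist(), "selected_down": down_idx.tolist(),
             "lifespan_set": np.sort(ls_idx).tolist()}
    return cfg, truth


def _all_null_config(n_per_cohort: int, seed: int) -> tuple[SimulationConfig, dict]:
    rng = np.random.default_rng(seed)
    m = 100
    zeros = np.zeros(m)
    cfg = SimulationConfig(
        n_per_cohort=n_per_cohort, baseline_freqs=rng.uniform(0.05, 0.95, m),
        s_true=zeros, u_true=zeros, beta_afb=zeros, beta_neb=zeros,
        beta_lifespan=zeros, h2=0.35, target_prevalence_cohort1=0.303,
        env_trend_per_year=0.0, pool_size=10 * m, seed=seed)
    return cfg, {"selected_up": [], "selected_down": [], "lifespan_set": []}


def _lifespan_confounded_config(n_per_cohort: int, seed: int
                                ) -> tuple[SimulationConfig, dict]:
    """Frequency trends driven by lifespan effects: the trending SNPs all carry
    strong negative parental-lifespan effects that the screen must catch."""
    rng = np.random.default_rng(seed)
    m = 40
    s = np.zeros(m)
    ls_idx = rng.choice(m, size=10, replace=False)
    s[ls_idx] = rng.uniform(0.06, 0.10, 10)
    freqs = rng.uniform(0.10, 0.90, m)
    freqs[ls_idx] = rng.uniform(0.30, 0.70, 10)
    beta_ls = np.zeros(m)
    beta_ls[ls_idx] = -rng.uniform(1.5, 2.5, 10)
    u = -rng.uniform(0.02, 0.08, m)
    cfg = SimulationConfig(
        n_per_cohort=n_per_cohort, baseline_freqs=freqs, s_true=s, u_true=u,
        beta_afb=np.zeros(m), beta_neb=np.zeros(m), beta_lifespan=beta_ls,
        h2=0.35, target_prevalence_cohort1=0.303, pool_size=10 * m, seed=seed)
    return cfg, {"selected_up": np.sort(ls_idx).tolist(), "selected_down": [],
                 "lifespan_set": np.sort(ls_idx).tolist()}


def generate_scenario(name: str, seed: int, out_dir: str | None = None,
                      n_per_cohort: int = 10_000
                      ) -> tuple[CohortDataset, pd.DataFrame, pd.DataFrame, dict]:
    """Build a named study scenario; optionally write it to ``out_dir``.

    Returns (dataset, panel, control pool, truth-index dict).
    """
    builders = {"paper_like": _paper_like_config, "all_null": _all_null_config,
                "lifespan_confounded": _lifespan_confounded_config}
    if name not in builders:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    cfg, truth = builders[name](n_per_cohort, seed)
    panel = make_panel(cfg)
    ss = np.random.SeedSequence([seed, 1_234_567])
    rng_data, rng_pool = [np.random.default_rng(s) for s in ss.spawn(2)]
    dataset = simulate_individuals(panel, cfg, rng=rng_data)
    pool = simulate_control_pool(cfg, panel, rng=rng_pool)
    if out_dir is not None:
        dataio.write_dataset(dataset, panel, out_dir)
        pool.to_csv(os.path.join(out_dir, "control_pool.tsv"), sep="\t",
                    index=False, float_format="%.10g")
        with open(os.path.join(out_dir, "scenario.json"), "w") as fh:
            json.dump({"name": name, "seed": seed,
                       "n_per_cohort": n_per_cohort, "truth": truth}, fh, indent=1)
    return dataset, panel, pool, truth


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, dataset: CohortDataset | None = None,
                 panel: pd.DataFrame | None = None,
                 pool: pd.DataFrame | None = None,
                 schedule: pd.DataFrame | None = None) -> dict:
    """Execute every stage on a dataset (in memory, or read from
    ``config.data_dir``); write per-stage TSVs plus ``report.json`` to
    ``config.out_dir`` and return the report dict."""
    os.makedirs(config.out_dir, exist_ok=True)
    if dataset is None:
        dataset, panel, schedule = dataio.read_dataset(config.data_dir)
        pool_path = os.path.join(config.data_dir, "control_pool.tsv")
        if os.path.exists(pool_path):
            pool = pd.read_csv(pool_path, sep="\t", dtype={"chrom": str})
    if schedule is None:
        schedule = (dataset.config.aging_schedule if dataset.config is not None
                    else None)
    if schedule is None:
        raise ValueError("no aging schedule available")

    ss = np.random.SeedSequence([config.seed, 99])
    rng_controls, rng_liab = [np.random.default_rng(s) for s in ss.spawn(2)]
    report: dict = {"config": _config_echo(config), "stages": {}}

    # --- stage 1: phenotype preparation -----------------------------------
    pheno, assignment = prepare_phenotypes(
        dataset.phenotypes, schedule, config.cohort_spec,
        min_cohort_n=config.min_cohort_n, myopia_cutoff=config.myopia_cutoff)
    retained = pheno["cohort"].to_numpy() >= 0
    geno = dataset.genotypes[retained]
    pheno = pheno.loc[retained].reset_index(drop=True)
    birth_years = pheno["birth_year"].to_numpy()
    cohort_index = pheno["cohort"].to_numpy()
    prev = cohort_prevalence(pheno["myopia"], cohort_index,
                             n_cohorts=len(config.cohort_spec))
    prev.to_csv(os.path.join(config.out_dir, "prevalence_observed.tsv"),
                sep="\t", index=False)
    report["stages"]["phenotypes"] = {
        "n_retained": int(retained.sum()),
        "exclusions": assignment.exclusions,
        "prevalence": prev["prevalence"].round(6).tolist(),
    }
    logger.info("phenotypes: %d retained, exclusions %s",
                retained.sum(), assignment.exclusions)

    # --- stage 2: association verification --------------------------------
    qc_report, qc_keep = qc_filter(geno, thresholds=config.qc,
                                   snp_ids=panel["snp_id"])
    qc_report.to_csv(os.path.join(config.out_dir, "qc.tsv"), sep="\t", index=False)
    covariates = pheno[["exam_age", "sex"] + [f"pc{i}" for i in range(1, 11)]
                       ].to_numpy(dtype=float)
    trait = pheno["spe40" if config.use_corrected_spe else "spe"].to_numpy()
    assoc = assoc_scan(geno, trait, covariates,
                       snp_ids=list(panel["snp_id"]), trait="refractive_error")
    assoc.loc[~qc_keep, ["beta", "se", "p"]] = np.nan

    ld_keep = np.zeros(len(panel), dtype=bool)
    qc_idx = np.flatnonzero(qc_keep)
    if qc_idx.size:
        ld_keep[qc_idx] = ld_prune(geno[:, qc_idx],
                                   assoc["p"].to_numpy()[qc_idx],
                                   positions=panel["pos"].to_numpy()[qc_idx],
                                   r2_threshold=config.r2_threshold)
    tested = qc_keep & ld_keep
    assoc["q"] = np.nan
    assoc.loc[tested, "q"] = bh_fdr(assoc.loc[tested, "p"])
    assoc = orient_risk_allele(assoc)  # dosages already count the risk allele
    verified = tested & (assoc["q"].to_numpy() < config.fdr_level) \
        & ~assoc["direction_discordant"].to_numpy()
    assoc["verified"] = verified
    assoc.to_csv(os.path.join(config.out_dir, "assoc_refraction.tsv"),
                 sep="\t", index=False)
    report["stages"]["verification"] = {
        "n_input": int(len(panel)), "n_qc_removed": int((~qc_keep).sum()),
        "n_ld_removed": int((qc_keep & ~ld_keep).sum()),
        "n_verified": int(verified.sum()),
    }
    logger.info("verification: %d -> %d SNPs", len(panel), verified.sum())
    vidx = np.flatnonzero(verified)
    vpanel = panel.iloc[vidx].reset_index(drop=True)
    vgeno = geno[:, vidx]

    # --- stage 3: selection scan + matched controls ------------------------
    estimates, scan_sum = scan_panel(
        vpanel, vgeno, birth_years, config.cohort_spec,
        fdr_level=config.fdr_level, generation_years=config.generation_years)
    estimates.to_csv(os.path.join(config.out_dir, "selection.tsv"),
                     sep="\t", index=False)
    report["stages"]["selection_scan"] = {
        "n_scanned": scan_sum.n_snps, "n_significant": scan_sum.n_significant,
        "n_up": scan_sum.n_up, "n_down": scan_sum.n_down,
        "sign_test_p": scan_sum.sign_test_p,
    }
    control_summary = None
    if pool is not None and config.n_control_sets > 0 and len(vpanel) > 0:
        sets = sample_matched_controls(vpanel, pool, config.n_control_sets,
                                       rng=rng_controls)
        control_summary = control_scan(pool, sets, birth_years,
                                       rng=rng_controls,
                                       fdr_level=config.fdr_level)
        control_summary.to_csv(os.path.join(config.out_dir, "control_summary.tsv"),
                               sep="\t", index=False)
        n_obs = scan_sum.n_significant
        exceed = int((control_summary["n_fdr_significant"] >= n_obs).sum())
        report["stages"]["matched_controls"] = {
            "n_sets": int(len(sets)),
            "mean_significant": float(control_summary["n_significant"].mean()),
            "mean_sig_increase": float(control_summary["n_sig_increase"].mean()),
            "mean_sig_decrease": float(control_summary["n_sig_decrease"].mean()),
            "n_sets_at_or_above_observed": exceed,
            "empirical_p": (exceed + 1) / (len(sets) + 1),
        }

    # --- stage 4: lifespan screen and exclusion ----------------------------
    ls_table, ls_flagged = lifespan_screen(vgeno, pheno, covariates,
                                           snp_ids=list(vpanel["snp_id"]),
                                           fdr_level=config.fdr_level)
    ls_table.to_csv(os.path.join(config.out_dir, "lifespan_screen.tsv"),
                    sep="\t", index=False)
    kept = ~ls_flagged
    est_kept = estimates.loc[kept].reset_index(drop=True)
    n_up = int((est_kept["direction"] == "+").sum())
    n_down = int((est_kept["direction"] == "-").sum())
    sign_p = binomial_sign_test(n_up, n_down) if n_up + n_down else float("nan")
    report["stages"]["lifespan_screen"] = {
        "n_flagged": int(ls_flagged.sum()),
        "flagged_snps": ls_table.loc[ls_flagged, "snp_id"].tolist(),
        "post_exclusion": {"n_up": n_up, "n_down": n_down, "sign_test_p": sign_p},
    }
    logger.info("lifespan screen: %d flagged; post-exclusion %d up / %d down",
                ls_flagged.sum(), n_up, n_down)

    # --- stage 5: reproductive pleiotropy ----------------------------------
    kidx = np.flatnonzero(kept)
    repro = reproductive_assoc(vgeno[:, kidx], pheno, covariates,
                               snp_ids=list(vpanel["snp_id"].iloc[kidx]),
                               fdr_level=config.fdr_level)
    selected = est_kept.loc[est_kept["direction"] != "0",
                            ["snp_id", "direction", "s"]]
    cons_table, cons_p = direction_consistency(selected, repro)
    pleio = repro.merge(est_kept[["snp_id", "direction", "s"]], on="snp_id")
    pleio.to_csv(os.path.join(config.out_dir, "pleiotropy.tsv"),
                 sep="\t", index=False)
    correlations = {}
    for tr in ("afb", "neb"):
        sub = pleio[(pleio["direction"] != "0") & pleio[f"{tr}_significant"]]
        if len(sub) >= 3:
            try:
                r, p, n = s_effect_correlation(sub["s"], sub[f"{tr}_beta"])
                correlations[tr] = {"r": r, "p": p, "n": n}
            except ValueError:
                pass
    myopic = pheno["myopia"].to_numpy(dtype=bool)
    group_tests = {}
    for tr in ("afb", "neb"):
        vals = pheno[tr].to_numpy(dtype=float)
        try:
            group_tests[tr] = group_t_test(vals[myopic], vals[~myopic])
        except ValueError:
            pass
    report["stages"]["pleiotropy"] = {
        "n_tested": int(len(repro)),
        "n_afb_significant": int(repro["afb_significant"].sum()),
        "n_neb_significant": int(repro["neb_significant"].sum()),
        "consistency_p": cons_p,
        "n_consistent": int((cons_table["consistent"] == True).sum()),  # noqa: E712
        "n_inconsistent": int((cons_table["consistent"] == False).sum()),  # noqa: E712
        "correlations": correlations,
        "group_t_tests": group_tests,
    }

    # --- stage 6: prevalence prediction ------------------------------------
    model_idx = kidx  # verified panel minus lifespan-flagged SNPs
    dos = vgeno[:, model_idx]
    nonmiss = (~np.isnan(dos)).sum(axis=0)
    ref_freq = np.clip(np.nansum(dos, axis=0) / (2 * nonmiss), 1e-6, 1 - 1e-6)
    betas = assoc["beta"].to_numpy()[vidx][model_idx]
    model = LiabilityModel(u=liability_effects_from_betas(betas, ref_freq),
                           p=ref_freq, h2=config.h2,
                           n_replicates=config.n_replicates, seed=config.seed)
    target = float(prev["prevalence"].iloc[0])
    pred = predict_prevalence(model, dos, cohort_index, target, rng=rng_liab)
    pred.to_csv(os.path.join(config.out_dir, "prevalence_predicted.tsv"),
                sep="\t", index=False)
    genetic_delta = 100.0 * (pred["mean_prevalence"].iloc[-1]
                             - pred["mean_prevalence"].iloc[0])
    total_delta = 100.0 * (prev["prevalence"].iloc[-1] - prev["prevalence"].iloc[0])
    cases = excess_cases(genetic_delta, config.population)
    frac = (fraction_of_increase(genetic_delta, total_delta)
            if total_delta != 0 else float("nan"))
    report["stages"]["prevalence_model"] = {
        "n_model_snps": int(len(model_idx)),
        "predicted": pred["mean_prevalence"].round(6).tolist(),
        "genetic_delta_points": genetic_delta,
        "total_delta_points": total_delta,
        "excess_cases": cases,
        "fraction_of_increase_pct": frac,
    }

    # --- terminal SNP categories (report completeness invariant) -----------
    category = np.full(len(panel), "not_verified", dtype=object)
    category[~qc_keep] = "qc_removed"
    category[qc_keep & ~ld_keep] = "ld_removed"
    category[vidx[ls_flagged]] = "lifespan_excluded"
    category[vidx[kept]] = "scanned"
    report["snp_categories"] = {
        cat: int((category == cat).sum())
        for cat in ("qc_removed", "ld_removed", "not_verified",
                    "lifespan_excluded", "scanned")}
    report["seed"] = config.seed

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonify)
    return report


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cohort_spec"] = [list(c) for c in config.cohort_spec]
    return d


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
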