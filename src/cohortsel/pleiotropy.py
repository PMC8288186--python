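"""Attribution of selection signals: lifespan screen, reproductive pleiotropy,
direction consistency, and control contrasts.

A frequency rise across birth cohorts is ambiguous on its own: the allele may
be positively selected through reproduction or early-life viability, or it may
shorten adult lifespan so that older cohorts are depleted of carriers at the
time of sampling.  The lifespan screen removes SNPs associated with parental
lifespan before the sign tests; the remaining signal is then attributed by
testing each SNP's association with age at first live birth (AFB) and number
of children ever born (NEB), and by checking that the direction of selection
agrees with the direction of the reproductive effect (antagonistic pleiotropy:
risk alleles for the disease trait carrying reproductive benefits).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import assoc_scan, bh_fdr

__all__ = ["lifespan_screen", "reproductive_assoc", "direction_consistency",
           "s_effect_correlation", "correlation_pvalue", "group_t_test",
           "association_proportion_chisq"]


def lifespan_screen(dosages: np.ndarray, pheno: pd.DataFrame,
                    covariates: np.ndarray | None = None,
                    snp_ids=None, fdr_level: float = 0.05
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Flag SNPs associated with the lifespan of either parent (FDR < level).

    Mother's and father's lifespans are tested separately (each BH-corrected
    across SNPs); a SNP is flagged if either parent's q-value is below the
    level.  Flagged SNPs are excluded from the selection panel downstream,
    since a lifespan effect can mimic a birth-cohort frequency trend.
    Returns (per-SNP table, flagged boolean mask).  If one parent's column is
    entirely missing the screen degrades to the other parent; if both are
    missing it returns an all-False mask.
    """
    m = dosages.shape[1]
    ids = snp_ids if snp_ids is not None else [str(j) for j in range(m)]
    out = pd.DataFrame({"snp_id": ids})
    flagged = np.zeros(m, dtype=bool)
    any_parent = False
    for parent, col in (("mother", "mother_lifespan"), ("father", "father_lifespan")):
        if col not in pheno.columns or pheno[col].notna().sum() == 0:
            continue
        any_parent = True
        res = assoc_scan(dosages, pheno[col].to_numpy(dtype=float),
                         covariates, snp_ids=ids, trait=f"{parent}_lifespan")
        q = bh_fdr(res["p"])
        out[f"{parent}_beta"] = res["beta"].to_numpy()
        out[f"{parent}_p"] = res["p"].to_numpy()
        out[f"{parent}_q"] = q
        flagged |= np.nan_to_num(q, nan=1.0) < fdr_level
    if not any_parent:
        import warnings
        warnings.warn("no parental lifespan data: lifespan screen skipped")
    out["lifespan_flagged"] = flagged
    return out, flagged


def reproductive_assoc(dosages: np.ndarray, pheno: pd.DataFrame,
                       covariates: np.ndarray | None = None,
                       snp_ids=None, fdr_level: float = 0.05) -> pd.DataFrame:
    """Per-SNP associations with AFB and NEB, each FDR-corrected separately.

    AFB is defined only for individuals with at least one child; its missing
    entries are handled by complete-case analysis inside the engine.
    """
    m = dosages.shape[1]
    ids = snp_ids if snp_ids is not None else [str(j) for j in range(m)]
    out = pd.DataFrame({"snp_id": pd.Series(ids, dtype=str)})
    for trait, col in (("afb", "afb"), ("neb", "neb")):
        res = assoc_scan(dosages, pheno[col].to_numpy(dtype=float),
                         covariates, snp_ids=ids, trait=trait)
        out[f"{trait}_beta"] = res["beta"].to_numpy()
        out[f"{trait}_p"] = res["p"].to_numpy()
        out[f"{trait}_q"] = bh_fdr(res["p"])
        out[f"{trait}_significant"] = np.nan_to_num(out[f"{trait}_q"], nan=1.0) < fdr_level
    return out


def direction_consistency(selection: pd.DataFrame, repro: pd.DataFrame
                          ) -> tuple[pd.DataFrame, float]:
    """Check that each selected SNP's reproductive effect explains its
    selection direction, and test the overall tally with an exact binomial.

    A positively selected risk allele is consistent if it significantly lowers
    AFB (earlier reproduction) or raises NEB (more children); a negatively
    selected allele, the reverse.  Consistency is defined only where the trait
    association is FDR-significant; each significant (SNP, trait) pair
    contributes one Bernoulli trial to the binomial test at null 0.5.
    """
    selection = selection.assign(snp_id=selection["snp_id"].astype(str))
    repro = repro.assign(snp_id=repro["snp_id"].astype(str))
    merged = selection.merge(repro, on="snp_id", how="inner")
    sel_dir = merged["direction"].astype(str)
    rows, n_cons, n_incons = [], 0, 0
    for _, r in merged.iterrows():
        if r["direction"] not in ("+", "-"):
            continue
        up = r["direction"] == "+"
        for trait, benefit_sign in (("afb", -1.0), ("neb", +1.0)):
            if not bool(r[f"{trait}_significant"]):
                verdict = None
            else:
                beneficial = benefit_sign * r[f"{trait}_beta"] > 0
                verdict = bool(beneficial == up)
                n_cons += verdict
                n_incons += not verdict
            rows.append({"snp_id": r["snp_id"], "direction": r["direction"],
                         "trait": trait, "beta": r[f"{trait}_beta"],
                         "q": r[f"{trait}_q"], "consistent": verdict})
    table = pd.DataFrame(rows, columns=["snp_id", "direction", "trait",
                                        "beta", "q", "consistent"])
    if n_cons + n_incons == 0:
        return table, np.nan
    k = min(n_cons, n_incons)
    p = float(min(1.0, 2.0 * stats.binom.cdf(k, n_cons + n_incons, 0.5)))
    return table, p


def correlation_pvalue(r: float, n: int) -> float:
    """Two-tailed p for a Pearson correlation via the t-transform:
    t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def s_effect_correlation(s_values, betas) -> tuple[float, float, int]:
    """Pearson correlation between selection coefficients and reproductive
    effect sizes among SNPs with significant effects; returns (r, p, n)."""
    s = np.asarray(s_values, dtype=float)
    b = np.asarray(betas, dtype=float)
    keep = ~(np.isnan(s) | np.isnan(b))
    s, b = s[keep], b[keep]
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(s) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(s, b)[0, 1])
    return r, correlation_pvalue(r, n), n


def group_t_test(values_a, values_b, equal_var: bool = False) -> dict:
    """Two-sample two-tailed t-test (Welch by default) with group summaries."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(t), "p": float(p),
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "se_a": float(a.std(ddof=1) / np.sqrt(len(a))),
            "se_b": float(b.std(ddof=1) / np.sqrt(len(b))),
            "n_a": len(a), "n_b": len(b)}


def association_proportion_chisq(k1: int, n1: int, k2: int, n2: int
                                 ) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) comparing the
    proportion of associated SNPs between two groups, e.g. the observed panel
    versus a matched random set."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be at least 1")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts exceed group sizes")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError("zero expected cell count")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
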