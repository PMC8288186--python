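"""Covariate-adjusted single-SNP association with QC, LD pruning and FDR.

One generic engine serves every trait in the pipeline: refractive error,
parental lifespans, age at first birth and number of children.  Effects are
ordinary least squares per risk-allele dosage with an intercept and arbitrary
covariate columns, two-tailed t-test on the dosage coefficient, complete-case
handling of missing genotypes and phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QCThresholds", "qc_filter", "linear_assoc", "assoc_scan",
           "ld_prune", "bh_fdr", "orient_risk_allele"]


@dataclass(frozen=True)
class QCThresholds:
    min_mac: int = 5          # minor allele count <5 fails
    max_missing: float = 0.05  # missing genotype rate >0.05 fails
    min_info: float = 0.3      # imputation info score <0.3 fails


def qc_filter(dosages: np.ndarray, info_scores: np.ndarray | None = None,
              thresholds: QCThresholds = QCThresholds(),
              snp_ids=None) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-SNP QC: minor allele count, missingness, imputation info.

    All three thresholds are strict inequalities and are checked in that
    order; a SNP carries at most one removal reason.  ``info_scores=None``
    skips the info check (directly genotyped data).  Returns the QC report
    and the boolean retained mask.
    """
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    nonmissing = (~np.isnan(dosages)).sum(axis=0)
    alt_count = np.nansum(dosages, axis=0)
    mac = np.minimum(alt_count, 2 * nonmissing - alt_count)
    missing_rate = 1.0 - nonmissing / n

    mac_fail = mac < thresholds.min_mac
    miss_fail = (missing_rate > thresholds.max_missing) & ~mac_fail
    if info_scores is not None:
        info = np.asarray(info_scores, dtype=float)
        info_fail = (info < thresholds.min_info) & ~mac_fail & ~miss_fail
    else:
        info = np.full(m, np.nan)
        info_fail = np.zeros(m, dtype=bool)

    retained = ~(mac_fail | miss_fail | info_fail)
    report = pd.DataFrame({
        "snp_id": snp_ids if snp_ids is not None else np.arange(m),
        "mac": mac, "missing_rate": missing_rate, "info": info,
        "mac_fail": mac_fail, "missing_fail": miss_fail, "info_fail": info_fail,
        "retained": retained,
    })
    return report, retained


def _ols_dosage(y: np.ndarray, dosage: np.ndarray, covariates: np.ndarray | None):
    """OLS of y on [1, dosage, covariates]; beta/se/p/n for the dosage term.

    Classical (homoskedastic) standard errors, two-tailed t-test — the
    textbook quantitative-association model.
    """
    keep = ~np.isnan(y) & ~np.isnan(dosage)
    if covariates is not None:
        keep &= ~np.isnan(covariates).any(axis=1)
    y, dosage = y[keep], dosage[keep]
    n = len(y)
    cols = [np.ones(n), dosage]
    if covariates is not None:
        cols.extend(covariates[keep].T)
    X = np.column_stack(cols)
    k = X.shape[1]
    if n < k + 1 or np.nanstd(dosage) == 0:
        return np.nan, np.nan, np.nan, n
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan, n
    # guard against collinearity that survives inversion numerically
    if np.linalg.cond(XtX) > 1e12:
        return np.nan, np.nan, np.nan, n
    beta_all = XtX_inv @ (X.T @ y)
    resid = y - X @ beta_all
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    beta = beta_all[1]
    if se == 0:
        return beta, se, np.nan, n
    p = 2.0 * stats.t.sf(abs(beta / se), n - k)
    return beta, se, p, n


def linear_assoc(dosage, phenotype, covariates=None, snp_id: str = "",
                 trait: str = "") -> dict:
    """Single-SNP association; returns a record with beta, se, p, n_used.

    Degenerate designs (constant dosage after complete-case filtering, or a
    covariate collinear with the dosage) yield NaN results flagged as
    ``degenerate`` rather than fabricated numbers.
    """
    dosage = np.asarray(dosage, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]
    beta, se, p, n = _ols_dosage(phenotype, dosage, cov)
    return {"snp_id": snp_id, "trait": trait, "beta": beta, "se": se,
            "p": p, "n_used": n, "degenerate": not np.isfinite(p)}


def assoc_scan(dosages: np.ndarray, phenotype, covariates=None,
               snp_ids=None, trait: str = "") -> pd.DataFrame:
    """Run :func:`linear_assoc` over the columns of a dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    ids = snp_ids if snp_ids is not None else [str(j) for j in range(m)]
    records = [linear_assoc(dosages[:, j], phenotype, covariates,
                            snp_id=ids[j], trait=trait) for j in range(m)]
    return pd.DataFrame.from_records(
        records, columns=["snp_id", "trait", "beta", "se", "p", "n_used",
                          "degenerate"])


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1.

    NaN entries (degenerate tests) are left NaN and do not count toward the
    number of tests.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    res = np.empty(m)
    res[order] = q
    out[ok] = res
    return out


def pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete."""
    df = pd.DataFrame(np.asarray(dosages, dtype=float))
    r = df.corr(min_periods=2).to_numpy()
    return r ** 2


def ld_prune(dosages: np.ndarray, pvals, positions=None,
             r2_threshold: float = 0.8, random_removal: bool = False,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """Greedy LD pruning: of any SNP pair with R^2 above the threshold, keep
    the one with the stronger association (smaller p).

    SNPs are visited in order of increasing p (ties broken by smaller genomic
    position, then column index) and kept only if not in high LD with any SNP
    already kept — equivalent to discarding the weaker member of every
    high-LD pair.  ``random_removal=True`` instead visits SNPs in random
    order, the robustness variant in which the removed member of a pair is
    effectively random.  Returns the boolean retained mask.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    r2 = pairwise_r2(dosages)
    if random_removal:
        rng = rng if rng is not None else np.random.default_rng()
        order = rng.permutation(m)
    else:
        pos = np.asarray(positions, dtype=float) if positions is not None else np.arange(m)
        order = np.lexsort((np.arange(m), pos, np.where(np.isnan(p), np.inf, p)))
    keep: list[int] = []
    for j in order:
        if all(not (r2[j, k] > r2_threshold) for k in keep):
            keep.append(j)
    mask = np.zeros(m, dtype=bool)
    mask[keep] = True
    return mask


def orient_risk_allele(assoc: pd.DataFrame, counted_is_risk=None) -> pd.DataFrame:
    """Orient refractive-error associations to the declared risk allele.

    ``counted_is_risk`` is a boolean per SNP saying whether the counted
    (dosage) allele is the declared risk allele; where it is not, the beta is
    negated so every beta is per risk allele.  A risk allele whose effect on
    refractive error is non-negative (not more myopic) is flagged
    direction-discordant; such SNPs fail verification downstream.
    """
    out = assoc.copy()
    if counted_is_risk is not None:
        flip = ~np.asarray(counted_is_risk, dtype=bool)
        out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out["direction_discordant"] = out["beta"] >= 0
    return out
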