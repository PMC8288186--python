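"""Allele-frequency trend scan across birth cohorts and selection-coefficient
estimation.

Under positive selection with a completely dominant advantageous allele
(fitness 1+s for carriers, 1 otherwise) the allele frequency p grows by
approximately p*s per generation, i.e. virtually linearly in calendar time
over a span of one generation.  The scan therefore regresses per-individual
risk-allele dosage/2 on birth year; the slope estimates the frequency change
per year, and s = slope * generation_years / p0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import bh_fdr

__all__ = ["cohort_allele_freq", "trend_test", "trend_test_matrix",
           "selection_coefficient", "binomial_sign_test",
           "sample_matched_controls", "scan_panel", "control_scan"]


def cohort_allele_freq(dosages: np.ndarray, cohort_mask: np.ndarray) -> np.ndarray:
    """Risk-allele frequency within a cohort: sum(dosage) / (2 * n_nonmissing).

    Works on a vector (one SNP) or an (n, m) matrix; SNP/cohort cells with no
    non-missing genotype come back NaN.
    """
    d = np.asarray(dosages, dtype=float)
    one_dim = d.ndim == 1
    if one_dim:
        d = d[:, None]
    sub = d[np.asarray(cohort_mask, dtype=bool)]
    n = (~np.isnan(sub)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(sub, axis=0) / (2.0 * n)
    freq[n == 0] = np.nan
    return freq[0] if one_dim else freq


def trend_test_matrix(dosages: np.ndarray, birth_years: np.ndarray) -> pd.DataFrame:
    """Vectorized per-SNP regression of dosage/2 on birth year.

    Returns slope_per_year, intercept, se, p (two-tailed test of zero slope)
    and n per SNP.  Constant dosage gives slope 0 with p NaN (flagged); fewer
    than two distinct birth years raises.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    x = np.asarray(birth_years, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("trend test needs at least two distinct birth years")
    y = d / 2.0
    mask = ~np.isnan(y)
    nj = mask.sum(axis=0).astype(float)
    xm = np.where(mask, x[:, None], 0.0)
    sx = xm.sum(axis=0)
    sxx = (xm * x[:, None]).sum(axis=0)
    sy = np.nansum(y, axis=0)
    sxy = np.nansum(y * x[:, None], axis=0)
    syy = np.nansum(y * y, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Sxx = sxx - sx * sx / nj
        Sxy = sxy - sx * sy / nj
        Syy = syy - sy * sy / nj
        slope = np.where(Sxx > 0, Sxy / np.where(Sxx > 0, Sxx, 1.0), np.nan)
        intercept = sy / nj - slope * sx / nj
        rss = np.maximum(Syy - slope * Sxy, 0.0)
        sigma2 = rss / (nj - 2)
        se = np.sqrt(sigma2 / Sxx)
    tstat = np.divide(slope, se, out=np.full_like(slope, np.nan), where=se > 0)
    p = 2.0 * stats.t.sf(np.abs(tstat), nj - 2)
    p[~np.isfinite(tstat)] = np.nan
    constant = Syy <= 0
    slope[constant & np.isfinite(slope)] = 0.0
    return pd.DataFrame({"slope_per_year": slope, "intercept": intercept,
                         "se": se, "p": p, "n": nj.astype(int)})


def trend_test(dosage, birth_years) -> tuple[float, float]:
    """Single-SNP convenience wrapper: (slope per year, two-tailed p)."""
    res = trend_test_matrix(np.asarray(dosage, dtype=float), birth_years)
    return float(res["slope_per_year"].iloc[0]), float(res["p"].iloc[0])


def selection_coefficient(slope_per_year, p0, generation_years: float = 25.0):
    """s = (frequency change per generation) / p0 = slope * g_years / p0."""
    p0 = np.asarray(p0, dtype=float)
    if np.any((p0 <= 0) | (p0 >= 1)):
        raise ValueError("p0 must lie strictly in (0, 1)")
    return np.asarray(slope_per_year, dtype=float) * generation_years / p0


def binomial_sign_test(n_up: int, n_down: int) -> float:
    """Exact two-tailed binomial test of up vs down counts at null 0.5.

    Two-tailed p = min(1, 2 * smaller tail); at a symmetric null this equals
    summing all equally extreme outcomes.
    """
    n = n_up + n_down
    if n < 1:
        raise ValueError("need at least one up or down call")
    k = min(n_up, n_down)
    return float(min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)))


def sample_matched_controls(panel: pd.DataFrame, pool: pd.DataFrame,
                            n_sets: int, freq_tol: float = 0.01,
                            rr_tol: float = 0.05,
                            rng: np.random.Generator | int | None = None,
                            max_retries: int = 20) -> list[np.ndarray]:
    """Random control sets matched on allele frequency and recombination rate.

    For every panel SNP, each set draws one pool SNP uniformly from those with
    |frequency difference| <= ``freq_tol`` and |recombination-rate difference|
    <= ``rr_tol`` cM/Mb, without replacement within a set (replacement is
    allowed across sets).  Returns one array of pool row indices per set.
    A panel SNP with no admissible pool match raises, naming the SNP.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pf = pool["baseline_freq"].to_numpy(dtype=float)
    pr = pool["recomb_rate"].to_numpy(dtype=float)
    admissible: list[np.ndarray] = []
    for _, snp in panel.iterrows():
        ok = (np.abs(pf - snp["baseline_freq"]) <= freq_tol) \
            & (np.abs(pr - snp["recomb_rate"]) <= rr_tol)
        cand = np.flatnonzero(ok)
        if cand.size == 0:
            raise ValueError(
                f"panel SNP {snp['snp_id']} has no admissible control "
                f"(freq within {freq_tol}, recomb rate within {rr_tol})")
        admissible.append(cand)
    # scarcest panel SNPs pick first to avoid spurious within-set depletion
    order = np.argsort([len(c) for c in admissible])
    sets = []
    for _ in range(n_sets):
        for _attempt in range(max_retries):
            chosen = np.full(len(panel), -1, dtype=int)
            used: set[int] = set()
            failed = False
            for j in order:
                free = [c for c in admissible[j] if c not in used]
                if not free:
                    failed = True
                    break
                pick = int(rng.choice(free))
                chosen[j] = pick
                used.add(pick)
            if not failed:
                sets.append(chosen)
                break
        else:
            raise ValueError("could not assemble a control set without "
                             "replacement; enlarge the control pool")
    return sets


@dataclass
class ScanSummary:
    n_snps: int
    n_significant: int
    n_up: int
    n_down: int
    sign_test_p: float


def scan_panel(panel: pd.DataFrame, dosages: np.ndarray, birth_years,
               cohort_spec, fdr_level: float = 0.05,
               generation_years: float = 25.0,
               p0_mode: str = "fitted") -> tuple[pd.DataFrame, ScanSummary]:
    """Trend-scan a SNP panel: per-cohort frequencies, per-year slope,
    BH-corrected trend p, direction among significant SNPs, and the
    selection coefficient per SNP.

    ``p0_mode='fitted'`` evaluates the baseline frequency for s = dp/p at the
    first cohort's midpoint year from the fitted line (less noisy than the
    raw cohort-1 frequency, ``p0_mode='raw'``).
    """
    birth_years = np.asarray(birth_years)
    if len(panel) == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=(str if c in ("snp_id", "direction") else float))
                              for c in ["snp_id", "slope_per_year", "trend_p",
                                        "trend_q", "direction", "p0", "s"]})
        return empty, ScanSummary(0, 0, 0, 0, np.nan)
    res = trend_test_matrix(dosages, birth_years)
    out = pd.DataFrame({"snp_id": panel["snp_id"].to_numpy()})
    for k, (a, b) in enumerate(cohort_spec):
        mask = (birth_years >= a) & (birth_years <= b)
        out[f"freq_c{k + 1}"] = cohort_allele_freq(dosages, mask)
    out["slope_per_year"] = res["slope_per_year"].to_numpy()
    out["trend_p"] = res["p"].to_numpy()
    out["trend_q"] = bh_fdr(out["trend_p"])

    mid1 = (cohort_spec[0][0] + cohort_spec[0][1]) / 2.0
    if p0_mode == "fitted":
        p0 = res["intercept"].to_numpy() + out["slope_per_year"].to_numpy() * mid1
    elif p0_mode == "raw":
        p0 = out["freq_c1"].to_numpy()
    else:
        raise ValueError(f"unknown p0_mode: {p0_mode!r}")
    p0 = np.clip(p0, 1e-6, 1 - 1e-6)
    out["p0"] = p0
    out["delta_p_per_generation"] = out["slope_per_year"] * generation_years
    out["s"] = out["delta_p_per_generation"] / p0

    sig = out["trend_q"].to_numpy() < fdr_level
    direction = np.where(~sig, "0",
                         np.where(out["slope_per_year"] > 0, "+", "-"))
    out["direction"] = direction
    n_up = int((direction == "+").sum())
    n_down = int((direction == "-").sum())
    sign_p = binomial_sign_test(n_up, n_down) if n_up + n_down > 0 else np.nan
    summary = ScanSummary(n_snps=len(panel), n_significant=int(sig.sum()),
                          n_up=n_up, n_down=n_down, sign_test_p=sign_p)
    return out, summary


def control_scan(pool: pd.DataFrame, control_sets: list[np.ndarray],
                 birth_years: np.ndarray, rng: np.random.Generator | int | None = None,
                 alpha: float = 0.05, fdr_level: float = 0.05,
                 dosage_source=None) -> pd.DataFrame:
    """Trend-scan each matched control set and summarize per set.

    ``dosage_source(snp_indices) -> (n, k) dosages`` supplies genotypes for
    pool SNPs; by default neutral Hardy-Weinberg dosages are drawn once per
    pool SNP (cached, so a SNP shared by two sets has identical genotypes,
    as it would in real data).  Reports per set the number of trend-significant
    SNPs at uncorrected ``alpha``, their up/down split, and the count at
    BH FDR < ``fdr_level`` within the set.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(birth_years)
    freqs = pool["baseline_freq"].to_numpy(dtype=float)
    cache: dict[int, np.ndarray] = {}

    def _default_source(snp_indices: np.ndarray) -> np.ndarray:
        cols = []
        for j in snp_indices:
            j = int(j)
            if j not in cache:
                cache[j] = rng.binomial(2, freqs[j], size=n).astype(float)
            cols.append(cache[j])
        return np.column_stack(cols)

    source = dosage_source if dosage_source is not None else _default_source
    rows = []
    for set_idx, snp_indices in enumerate(control_sets):
        d = source(np.asarray(snp_indices))
        res = trend_test_matrix(d, birth_years)
        p = res["p"].to_numpy()
        slope = res["slope_per_year"].to_numpy()
        sig = p < alpha
        q = bh_fdr(p)
        rows.append({
            "set": set_idx,
            "n_significant": int(np.nansum(sig)),
            "n_sig_increase": int(np.nansum(sig & (slope > 0))),
            "n_sig_decrease": int(np.nansum(sig & (slope < 0))),
            "n_fdr_significant": int(np.nansum(q < fdr_level)),
        })
    return pd.DataFrame(rows)
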