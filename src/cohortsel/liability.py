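"""Liability-threshold prediction of disease prevalence from genotypes.

The additive model standardizes each genotype to w = (x - 2p)/sqrt(2p(1-p))
(mean 0, variance 1 under Hardy-Weinberg at frequency p) and forms a liability
score y_j = sum_i w_ij * u_i + eps_j, where eps is Gaussian with variance
var(sum w*u) * (1/h2 - 1) so that the genetic score explains exactly h2 of the
liability variance.  A threshold y0 is calibrated on a reference cohort so the
fraction with y > y0 equals that cohort's observed prevalence; the same y0,
applied to later cohorts whose risk-allele frequencies have shifted, converts
the genetic change into a predicted change in prevalence.  The residual draw
and calibration are repeated over replicates and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LiabilityModel", "standardized_weight", "residual_variance",
           "calibrate_threshold", "predict_prevalence",
           "liability_effects_from_betas", "excess_cases",
           "fraction_of_increase"]


def standardized_weight(x, p):
    """GCTA-style standardized genotype w = (x - 2p)/sqrt(2p(1-p)).

    Under Hardy-Weinberg at frequency p, w has population mean 0 and
    variance 1.  p must lie strictly in (0, 1).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("reference frequency must lie strictly in (0, 1)")
    x = np.asarray(x, dtype=float)
    return (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def residual_variance(var_genetic: float, h2: float) -> float:
    """Residual liability variance var_g * (1/h2 - 1); total variance var_g/h2."""
    if not (0 < h2 <= 1):
        raise ValueError("h2 must lie in (0, 1]")
    if var_genetic < 0:
        raise ValueError("genetic variance must be non-negative")
    return var_genetic * (1.0 / h2 - 1.0)


def calibrate_threshold(scores, target_prevalence: float) -> float:
    """Threshold y0 such that the fraction of scores strictly above y0 equals
    the target prevalence (empirical (1 - target)-quantile)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot calibrate on an empty reference cohort")
    if not (0 < target_prevalence < 1):
        if target_prevalence == 0:
            return float(np.max(scores)) + 1.0
        raise ValueError("target prevalence must lie in (0, 1)")
    return float(np.quantile(scores, 1.0 - target_prevalence))


def liability_effects_from_betas(betas_spe, freqs) -> np.ndarray:
    """Convert per-dosage refractive-error effects (diopters per risk allele,
    negative = more myopic) to standardized liability effects, risk-positive:
    u_i = -beta_i * sqrt(2 p_i (1 - p_i))."""
    betas = np.asarray(betas_spe, dtype=float)
    p = np.asarray(freqs, dtype=float)
    return -betas * np.sqrt(2.0 * p * (1.0 - p))


@dataclass
class LiabilityModel:
    """Per-SNP standardized effects with reference frequencies and h2.

    ``u`` is on the standardized-genotype scale with higher liability = higher
    disease risk; ``p`` is the whole-sample reference frequency of the counted
    (risk) allele, one value per SNP, so cohort differences enter the
    prediction only through the genotypes.
    """

    u: np.ndarray
    p: np.ndarray
    h2: float = 0.35
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.u.shape != self.p.shape:
            raise ValueError("u and p must have one entry per SNP")
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise ValueError("reference frequencies must lie strictly in (0, 1)")
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must lie in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def genetic_scores(self, dosages: np.ndarray) -> np.ndarray:
        """sum_i w_ij u_i with missing genotypes imputed to 2p (w = 0)."""
        d = np.asarray(dosages, dtype=float)
        w = standardized_weight(np.where(np.isnan(d), 2.0 * self.p, d), self.p)
        return w @ self.u


def predict_prevalence(model: LiabilityModel, dosages: np.ndarray,
                       cohort_index: np.ndarray, target_prevalence: float,
                       reference_cohort: int = 0,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-cohort predicted prevalence, averaged over residual replicates.

    Each replicate draws fresh residuals for everyone, calibrates y0 on the
    reference cohort to the target prevalence, and applies that same y0 to
    every cohort.  Reports mean prevalence and its standard error over
    replicates per cohort; empty cohorts are skipped with a warning.
    """
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    cohort_index = np.asarray(cohort_index)
    g = model.genetic_scores(dosages)
    var_g = float(np.var(g))
    sd_e = np.sqrt(residual_variance(var_g, model.h2)) if var_g > 0 else 1.0

    cohorts = [k for k in np.unique(cohort_index) if k >= 0]
    ref_mask = cohort_index == reference_cohort
    if not ref_mask.any():
        raise ValueError(f"reference cohort {reference_cohort} is empty")
    masks = {}
    for k in cohorts:
        mask = cohort_index == k
        if not mask.any():
            import warnings
            warnings.warn(f"cohort {k} is empty; skipped")
            continue
        masks[k] = mask

    prev = np.zeros((model.n_replicates, len(masks)))
    for r in range(model.n_replicates):
        y = g + rng.normal(0.0, sd_e, size=len(g))
        y0 = calibrate_threshold(y[ref_mask], target_prevalence)
        for c, (k, mask) in enumerate(masks.items()):
            prev[r, c] = float(np.mean(y[mask] > y0))
    rows = []
    for c, (k, mask) in enumerate(masks.items()):
        rows.append({"cohort": int(k), "n": int(mask.sum()),
                     "mean_prevalence": float(prev[:, c].mean()),
                     "se": float(prev[:, c].std(ddof=1) / np.sqrt(model.n_replicates))
                     if model.n_replicates > 1 else np.nan})
    return pd.DataFrame(rows)


def excess_cases(delta_prevalence_points: float, population: int) -> int:
    """Disease cases added by a prevalence increment of ``delta`` percentage
    points in a population: round(population * delta / 100)."""
    if population < 0:
        raise ValueError("population must be non-negative")
    return int(round(population * delta_prevalence_points / 100.0))


def fraction_of_increase(genetic_delta_points: float, total_delta_points: float) -> float:
    """Share (percent) of the total prevalence increase attributable to the
    genetic increment: 100 * genetic / total."""
    if total_delta_points == 0:
        raise ValueError("total prevalence change is zero: fraction undefined")
    return 100.0 * genetic_delta_points / total_delta_points
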