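"""Refraction phenotype preparation.

Spherical equivalent (SpE), the single-number summary of refractive error, is
sphere power plus half the cylinder power, averaged over the two eyes.  Because
adult refraction drifts hyperopically with age and individuals are examined at
different ages, the observed SpE is corrected back to age 40 using a supplied
five-year aging schedule before myopia (SpE < -0.5 D, strict) is called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

MYOPIA_CUTOFF_D = -0.5


def spherical_equivalent(sphere_r, cyl_r, sphere_l, cyl_l) -> np.ndarray:
    """Mean over eyes of sphere + cylinder/2 (diopters).

    Any missing eye value yields NaN; such records are excluded downstream.
    Accepts scalars or arrays.
    """
    se_r = np.asarray(sphere_r, dtype=float) + np.asarray(cyl_r, dtype=float) / 2.0
    se_l = np.asarray(sphere_l, dtype=float) + np.asarray(cyl_l, dtype=float) / 2.0
    return (se_r + se_l) / 2.0


def correct_to_age40(spe, exam_age, schedule: pd.DataFrame) -> np.ndarray:
    """Remove the accumulated hyperopic aging shift between age 40 and exam age.

    The schedule gives the SpE change per five-year age band
    (columns ``age_start, age_end, delta_spe_per_5y``); the shift is prorated
    linearly inside bands.  Exam ages below 40 or beyond the schedule raise.
    """
    spe = np.asarray(spe, dtype=float)
    exam_age = np.asarray(exam_age, dtype=float)
    valid = ~np.isnan(exam_age)
    if np.any(exam_age[valid] < 40):
        raise ValueError("exam_age below 40: correction to age 40 undefined")
    max_age = float(schedule["age_end"].max())
    if np.any(exam_age[valid] > max_age):
        raise ValueError(f"exam_age beyond aging schedule (max {max_age})")
    shift = np.zeros_like(spe)
    for _, band in schedule.iterrows():
        lo, hi = float(band["age_start"]), float(band["age_end"])
        overlap = np.clip(np.minimum(exam_age, hi) - np.maximum(40.0, lo), 0.0, None)
        shift += float(band["delta_spe_per_5y"]) * overlap / (hi - lo)
    return spe - shift


def call_myopia(spe40, cutoff: float = MYOPIA_CUTOFF_D) -> np.ndarray:
    """Myopia indicator: SpE at age 40 strictly below the cutoff (default -0.5 D)."""
    return np.asarray(spe40, dtype=float) < cutoff


@dataclass
class CohortAssignment:
    """Per-individual cohort labels plus the exclusion ledger."""

    cohort_index: pd.Series          # -1 where excluded
    cohorts: pd.DataFrame            # start_year, end_year, midpoint_year, n
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def retained(self) -> np.ndarray:
        return (self.cohort_index.to_numpy() >= 0)


def assign_cohorts(birth_years, cohort_spec, min_n: int = 100) -> CohortAssignment:
    """Assign individuals to birth cohorts; drop out-of-range individuals and
    birth years represented by fewer than ``min_n`` individuals.

    Mirrors the study design in which single birth years at the edges of the
    sampling frame are too sparse to contribute a stable cohort frequency.
    """
    by = pd.Series(birth_years).astype(int)
    idx = np.full(len(by), -1, dtype=int)
    for k, (a, b) in enumerate(cohort_spec):
        idx[(by >= a) & (by <= b)] = k
    n_outside = int((idx < 0).sum())

    counts = by.value_counts()
    small_years = set(counts.index[counts < min_n])
    small_mask = by.isin(small_years).to_numpy() & (idx >= 0)
    n_small = int(small_mask.sum())
    idx[small_mask] = -1

    if not (idx >= 0).any():
        raise ValueError("no individuals retained after cohort assignment")

    rows = []
    for k, (a, b) in enumerate(cohort_spec):
        rows.append({"start_year": a, "end_year": b,
                     "midpoint_year": (a + b) / 2.0,
                     "n": int((idx == k).sum())})
    return CohortAssignment(
        cohort_index=pd.Series(idx, index=by.index),
        cohorts=pd.DataFrame(rows),
        exclusions={"outside_cohorts": n_outside, "small_birth_year": n_small},
    )


def cohort_prevalence(myopic, cohort_index, n_cohorts: int | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-cohort myopia prevalence with Wilson score confidence intervals."""
    myopic = np.asarray(myopic, dtype=bool)
    cohort_index = np.asarray(cohort_index)
    if n_cohorts is None:
        n_cohorts = int(cohort_index.max()) + 1
    rows = []
    for k in range(n_cohorts):
        mask = cohort_index == k
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"cohort {k} is empty")
        m = int(myopic[mask].sum())
        lo, hi = proportion_confint(m, n, alpha=alpha, method="wilson")
        rows.append({"cohort": k, "n": n, "n_myopic": m,
                     "prevalence": m / n, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def prepare_phenotypes(pheno: pd.DataFrame, schedule: pd.DataFrame,
                       cohort_spec, min_cohort_n: int = 100,
                       myopia_cutoff: float = MYOPIA_CUTOFF_D,
                       exclude: np.ndarray | None = None) -> tuple[pd.DataFrame, CohortAssignment]:
    """Full preparation pass: SpE, correction to 40, myopia call, cohorts.

    Returns a copy of the table with ``spe``, ``spe40``, ``myopia`` and
    ``cohort`` columns, and the cohort assignment (with exclusion counts,
    including records dropped for incomplete refraction or a caller-supplied
    exclusion flag such as eye-surgery history).
    """
    df = pheno.copy()
    df["spe"] = spherical_equivalent(df["sphere_R"], df["cyl_R"],
                                     df["sphere_L"], df["cyl_L"])
    df["spe40"] = correct_to_age40(df["spe"], df["exam_age"], schedule)
    df["myopia"] = call_myopia(df["spe40"], cutoff=myopia_cutoff)

    assignment = assign_cohorts(df["birth_year"], cohort_spec, min_n=min_cohort_n)
    df["cohort"] = assignment.cohort_index.to_numpy()

    incomplete = df["spe"].isna().to_numpy()
    assignment.exclusions["incomplete_refraction"] = int(
        (incomplete & assignment.retained).sum())
    drop = incomplete
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        assignment.exclusions["flagged_by_caller"] = int(
            (exclude & ~incomplete & assignment.retained).sum())
        drop = drop | exclude
    df.loc[drop, "cohort"] = -1
    return df, assignment
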