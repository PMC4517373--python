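"""High-level drivers tying the stages together: impute -> estimate ->
pool -> compare.  Used by the command-line interface, the sensitivity
protocols and the examples."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort
from .estimators import (
    DAYS_PER_YEAR, LifeTable, SurvivalCurve, cause_specific_km,
    cumulative_incidence, kaplan_meier, pohar_perme,
)
from .mice import ImputationResult, ImputationSpec, run_chained_equations
from .pooling import PooledCurve, pool_survival_curves

DEFAULT_REPORT_YEARS = (1, 3, 5, 10)
DEFAULT_AGE_STRATA = ((56.0, 65.0), (65.0, 70.0), (70.0, np.inf))


def per_dataset_curves(result: ImputationResult, estimator: str = "km",
                       rows: pd.Series | None = None) -> list[SurvivalCurve]:
    """Cause-specific curves for each completed dataset.

    ``estimator='km'`` censors other-cause deaths; ``'cr'`` returns the
    competing-risks survival 1 - CIF_prostate.  ``rows`` optionally
    restricts to a subset of subjects (e.g. an age stratum).
    """
    curves = []
    for df in result.completed:
        sub = df if rows is None else df.loc[rows]
        if estimator == "km":
            curves.append(cause_specific_km(sub["followup_days"], sub["dead"], sub["cause"]))
        elif estimator == "cr":
            curves.append(
                cumulative_incidence(sub["followup_days"], sub["dead"], sub["cause"])
                .survival_complement("prostate")
            )
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    return curves


def pooled_cause_specific(result: ImputationResult, estimator: str = "km",
                          rows: pd.Series | None = None) -> PooledCurve:
    return pool_survival_curves(per_dataset_curves(result, estimator, rows))


def run_mi_pipeline(cohort: Cohort, spec: ImputationSpec | None = None,
                    matrix: pd.DataFrame | None = None) -> tuple[ImputationResult, PooledCurve, PooledCurve]:
    """Impute, then pool the cause-specific KM and competing-risks curves."""
    result = run_chained_equations(cohort, spec, matrix)
    return result, pooled_cause_specific(result, "km"), pooled_cause_specific(result, "cr")


def survival_comparison(
    cohort: Cohort,
    result: ImputationResult,
    life_table: LifeTable | None = None,
    report_years=DEFAULT_REPORT_YEARS,
    age_strata=None,
) -> pd.DataFrame:
    """The four-estimator summary: overall KM, Pohar-Perme net survival,
    pooled cause-specific KM and pooled competing-risks survival at the
    report times, overall and (optionally) by age stratum."""
    df = cohort.data
    frames = []
    strata: list[tuple[str, pd.Series]] = [("all", pd.Series(True, index=df.index))]
    if age_strata:
        for lo, hi in age_strata:
            label = f"({lo:g},{hi:g}]" if np.isfinite(hi) else f"({lo:g},inf)"
            strata.append((label, (df["age_at_diagnosis"] > lo) & (df["age_at_diagnosis"] <= hi)))
        strata[1] = (f"[{age_strata[0][0]:g},{age_strata[0][1]:g}]",
                     (df["age_at_diagnosis"] >= age_strata[0][0])
                     & (df["age_at_diagnosis"] <= age_strata[0][1]))
    days = np.asarray(report_years, dtype=float) * DAYS_PER_YEAR
    for label, rows in strata:
        sub = df.loc[rows]
        overall = kaplan_meier(sub["followup_days"], sub["dead"])
        vals = {"overall": overall.evaluate(days)}
        if life_table is not None:
            net = pohar_perme(sub["followup_days"], sub["dead"], sub["age_at_diagnosis"],
                              sub["diagnosis_year"], sub["sex"], life_table)
            vals["net"] = net.evaluate(days)
        vals["pooled_km"] = pooled_cause_specific(result, "km", rows).evaluate(days)
        vals["pooled_cr"] = pooled_cause_specific(result, "cr", rows).evaluate(days)
        frame = pd.DataFrame(vals)
        frame.insert(0, "stratum", label)
        frame.insert(1, "years", report_years)
        frame.insert(2, "n", int(rows.sum()))
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
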