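"""Cohort data model: ingestion, validation, coding rules and derived variables.

A cohort is one row per man diagnosed with prostate cancer, carrying
follow-up time (days), vital status, cause of death (possibly missing),
and the clinical covariates used by the imputation model: PSA at
diagnosis, clinical stage (cT, cN, cM), first treatment, Gleason risk
group, pathological stage (pT, pN — defined only after surgery), PSA
after treatment, age at diagnosis and diagnosis year.

Record-level rules enforced at ingestion:

* zero-duration follow-up is excluded (and counted);
* a cause of death implies the subject died;
* pathological stage implies the first treatment was surgery.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# category supports (string labels in files; order is the display order)
CT_LEVELS = ["1a", "1b", "1c", "2a", "2b", "2c", "3a", "3b", "4"]
PT_LEVELS = ["2a", "2b", "2c", "3a", "3b", "4"]
TREATMENT_LEVELS = ["surgery", "radiotherapy", "hormone+chemo", "surveillance+HIFU"]
GLEASON_LEVELS = ["low", "intermediate", "high"]
CAUSE_LEVELS = ["prostate", "other"]
DAMICO_LEVELS = ["low", "intermediate", "high+locally_advanced", "N+M+"]

CATEGORY_LEVELS: dict[str, list[str]] = {
    "cT": CT_LEVELS,
    "pT": PT_LEVELS,
    "first_treatment": TREATMENT_LEVELS,
    "gleason_group": GLEASON_LEVELS,
    "cause": CAUSE_LEVELS,
}

CONTINUOUS_FIELDS = ["age_at_diagnosis", "psa_diag", "psa_post"]
BINARY_FIELDS = ["cN", "cM", "pN", "dead"]
CATEGORICAL_FIELDS = ["cT", "first_treatment", "gleason_group", "pT", "cause"]

FIELDS = [
    "id", "age_at_diagnosis", "psa_diag", "cT", "cN", "cM", "first_treatment",
    "gleason_group", "pT", "pN", "psa_post", "followup_days", "dead", "cause",
    "sex", "diagnosis_year",
]

#: variables the imputation engine may touch, in the clinical visit order
IMPUTABLE_VARIABLES = [
    "psa_diag", "cT", "cN", "cM", "gleason_group", "first_treatment",
    "pT", "pN", "psa_post", "cause",
]
PASSIVE_VARIABLES = ["T_new", "N_new", "damico_group"]


def round_half_up(x, decimals: int = 1):
    """Decimal rounding with ties away from zero (display convention)."""
    factor = 10.0**decimals
    x = np.asarray(x, dtype=float)
    return np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)


class CohortValidationError(ValueError):
    pass


@dataclass
class Cohort:
    """An ordered collection of patient records backed by a DataFrame."""

    data: pd.DataFrame
    provenance: str = ""
    n_excluded_zero_followup: int = 0

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        validate_records(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_dead(self) -> int:
        return int((self.data["dead"] == 1).sum())

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), provenance=self.provenance,
                      n_excluded_zero_followup=self.n_excluded_zero_followup)

    def with_derived(self) -> "Cohort":
        """Return a copy carrying the passive variables T_new / N_new / d'Amico."""
        df = self.data.copy()
        derived = derive_covariates(df)
        for col in derived.columns:
            df[col] = derived[col]
        out = Cohort.__new__(Cohort)
        out.data = df
        out.provenance = self.provenance
        out.n_excluded_zero_followup = self.n_excluded_zero_followup
        return out

    def write(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index=False)


def validate_records(df: pd.DataFrame) -> None:
    missing_cols = [c for c in FIELDS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing required columns: {missing_cols}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()[:5]
        raise CohortValidationError(f"duplicate patient ids, e.g. {dupes}")
    fu = pd.to_numeric(df["followup_days"], errors="coerce")
    if fu.isna().any() or (fu < 1).any():
        bad = df.index[fu.isna() | (fu < 1)].tolist()[:10]
        raise CohortValidationError(f"followup_days must be integers >= 1 (rows {bad})")
    dead = df["dead"]
    if not dead.isin([0, 1]).all():
        raise CohortValidationError("dead must be 0/1")
    bad_cause = df["cause"].notna() & (dead != 1)
    if bad_cause.any():
        rows = df.index[bad_cause].tolist()[:10]
        raise CohortValidationError(f"cause of death present for living subjects (rows {rows})")
    surgery = df["first_treatment"] == "surgery"
    bad_path = (df["pT"].notna() | df["pN"].notna()) & ~surgery
    if bad_path.any():
        rows = df.index[bad_path].tolist()[:10]
        raise CohortValidationError(
            f"pathological stage present without surgery as first treatment (rows {rows})"
        )
    for var, levels in CATEGORY_LEVELS.items():
        vals = df[var].dropna()
        unknown = set(map(str, vals.unique())) - set(levels)
        if unknown:
            raise CohortValidationError(f"unknown level(s) {sorted(unknown)} for variable {var!r}")
    for var in ("cN", "cM", "pN"):
        vals = df[var].dropna()
        if not vals.isin([0, 1]).all():
            raise CohortValidationError(f"{var} must be binary 0/1")
    for var in ("psa_diag", "psa_post"):
        vals = pd.to_numeric(df[var], errors="coerce")
        if (vals.dropna() < 0).any():
            raise CohortValidationError(f"{var} must be nonnegative")


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    bad_rows: list[int] = []
    for col in ("age_at_diagnosis", "psa_diag", "psa_post", "followup_days",
                "dead", "diagnosis_year", "cN", "cM", "pN"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            bad_rows.extend(df.index[bad].tolist())
            df[col] = coerced
    if bad_rows:
        raise CohortValidationError(
            f"unparseable numeric values in rows {sorted(set(bad_rows))[:20]}"
        )
    for col in CATEGORICAL_FIELDS:
        if col in df.columns:
            df[col] = df[col].astype(object).where(df[col].notna(), np.nan)
            df[col] = df[col].map(lambda v: str(v) if not pd.isna(v) else np.nan)
    df["followup_days"] = df["followup_days"].astype(int)
    df["dead"] = df["dead"].astype(int)
    df["diagnosis_year"] = df["diagnosis_year"].astype(int)
    return df


def read_cohort(
    path,
    sep: str | None = None,
    column_map: dict[str, str] | None = None,
    na_values=("", "NA", "."),
    provenance: str | None = None,
    config: str | None = None,
) -> Cohort:
    """Read a delimited cohort file (comma or tab; sniffed when ``sep`` is None).

    ``column_map`` maps file header names onto the canonical field names.
    ``config`` optionally names a YAML file with keys ``column_map``,
    ``na_values`` and ``sep`` (explicit arguments win).  Records with
    followup_days <= 0 are excluded and the exclusion count is logged and
    kept on the returned cohort.
    """
    if config is not None:
        import yaml

        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
        column_map = column_map or cfg.get("column_map")
        na_values = tuple(cfg.get("na_values", na_values))
        sep = sep or cfg.get("sep")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     na_values=list(na_values), keep_default_na=True)
    if column_map:
        df = df.rename(columns=column_map)
    if "sex" not in df.columns:
        df["sex"] = "male"
    if "id" not in df.columns:
        raise CohortValidationError("cohort file must contain an 'id' column")
    df = _coerce_types(df)
    fu = df["followup_days"]
    excluded = int((fu <= 0).sum())
    if excluded:
        logger.info("excluded %d record(s) with zero or negative follow-up", excluded)
        df = df[fu > 0].reset_index(drop=True)
    return Cohort(df, provenance=provenance or str(path), n_excluded_zero_followup=excluded)


def followup_days_from_dates(diagnosis_date: str, end_date: str) -> int:
    """Days between two ISO-8601 dates (diagnosis -> death/last news/censor)."""
    d0 = _dt.date.fromisoformat(diagnosis_date)
    d1 = _dt.date.fromisoformat(end_date)
    return (d1 - d0).days


def code_cause_of_death(raw_cause, part1_mentions_cancer) -> str | float:
    """Trichotomise a death-certificate cause for a deceased subject.

    ``prostate`` if the underlying cause is prostate cancer or prostate
    cancer is mentioned in part 1 of the certificate; ``other`` for any
    other observed cause; missing (NaN) when no cause was observed.
    """
    part1 = bool(part1_mentions_cancer)
    if raw_cause is None or (isinstance(raw_cause, float) and np.isnan(raw_cause)) or raw_cause == "":
        return "prostate" if part1 else np.nan
    raw = str(raw_cause).strip().lower()
    if raw in {"prostate", "prostate cancer", "c61"} or part1:
        return "prostate"
    return "other"


# ---------------------------------------------------------------------------
# Derived variables (passive in the imputation model)

#: d'Amico risk rules, reconstructed from the standard criteria and
#: configurable: each entry is (group, predicate-kwargs).  N+ or M+
#: overrides the PSA/Gleason/stage rules.
HIGH_CT = {"2c", "3a", "3b", "4"}
LOW_CT = {"1a", "1b", "1c", "2a"}


def damico_group(psa, gleason, cT, cN, cM):
    """Standard d'Amico grouping with an overriding node/metastasis class.

    low: PSA <= 10 and Gleason low and cT <= 2a;
    intermediate: PSA in (10, 20] or Gleason intermediate or cT 2b;
    high + locally advanced: PSA > 20 or Gleason high or cT >= 2c;
    N+M+: cN = 1 or cM = 1 (overrides the others).
    Any needed component missing -> missing.
    """
    if not pd.isna(cN) and int(cN) == 1 or (not pd.isna(cM) and int(cM) == 1):
        return "N+M+"
    if pd.isna(cN) or pd.isna(cM) or pd.isna(psa) or pd.isna(gleason) or pd.isna(cT):
        return np.nan
    cT = str(cT)
    if psa > 20 or gleason == "high" or cT in HIGH_CT:
        return "high+locally_advanced"
    if psa > 10 or gleason == "intermediate" or cT == "2b":
        return "intermediate"
    return "low"


def derive_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Compute the passive variables T_new, N_new and the d'Amico group.

    T_new/N_new equal the pathological stage when the first treatment is
    surgery, and the clinical stage otherwise.  Surgery records with both
    stages missing are flagged (logged) and left missing.
    """
    surgery = df["first_treatment"] == "surgery"
    t_new = np.where(surgery & df["pT"].notna(), df["pT"], df["cT"])
    n_new = np.where(surgery & df["pN"].notna(), df["pN"], df["cN"])
    flagged = surgery & df["pT"].isna() & df["cT"].isna()
    if flagged.any():
        logger.info("%d surgery record(s) with both pT and cT missing; T_new left missing",
                    int(flagged.sum()))
    dam = [
        damico_group(p, g, t, n, m)
        for p, g, t, n, m in zip(df["psa_diag"], df["gleason_group"], df["cT"], df["cN"], df["cM"])
    ]
    out = pd.DataFrame(index=df.index)
    out["T_new"] = pd.Series(t_new, index=df.index).where(pd.Series(t_new, index=df.index).notna(), np.nan)
    out["N_new"] = pd.to_numeric(pd.Series(n_new, index=df.index), errors="coerce")
    out["damico_group"] = dam
    return out


# ---------------------------------------------------------------------------
# Missingness bookkeeping

#: denominator conventions: all patients, the deceased only for the cause
#: of death, surgery patients only for the pathological stage
_DENOMINATORS = {
    "cause": lambda df: df["dead"] == 1,
    "pT": lambda df: df["first_treatment"] == "surgery",
    "pN": lambda df: df["first_treatment"] == "surgery",
}


def missingness_summary(cohort: Cohort | pd.DataFrame, variables=None) -> pd.DataFrame:
    """Per-variable missing counts with the usual denominator conventions.

    Percentages are half-up rounded to one decimal.
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    variables = variables or IMPUTABLE_VARIABLES
    rows = []
    for var in variables:
        mask = _DENOMINATORS[var](df) if var in _DENOMINATORS else pd.Series(True, index=df.index)
        denom = int(mask.sum())
        n_missing = int(df.loc[mask, var].isna().sum())
        pct = float(round_half_up(100.0 * n_missing / denom, 1)) if denom else np.nan
        rows.append((var, denom, n_missing, pct))
    return pd.DataFrame(rows, columns=["variable", "denominator", "n_missing", "percent"])
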