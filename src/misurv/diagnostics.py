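"""MCAR-vs-MAR screening in the style of Dixon's battery of tests.

For a target variable with missing values, the cohort is split by the
target's missingness indicator and each companion variable is compared
between the two groups: Mann-Whitney-Wilcoxon for continuous companions,
Fisher's exact test for categorical ones (exact for 2x2 tables,
seeded Monte-Carlo permutation for larger ones).  Non-significance of
every test (after a multiplicity correction) is consistent with MCAR;
any significant test is evidence that the missingness depends on
observed data (MAR) or on the missing values themselves (MNAR — not
distinguishable from MAR by any test on the observed data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, round_half_up
from .mice import _CAT_LEVELS

CONTINUOUS_COMPANIONS = {"age_at_diagnosis", "psa_diag", "psa_post", "followup_days"}


@dataclass
class MissingnessTestReport:
    target: str
    tests: pd.DataFrame   # companion, test, statistic, p_value, p_adjusted, note
    alpha: float
    multiplicity: str
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        sig = self.tests["p_adjusted"].dropna() < self.alpha
        self.verdict = "evidence-against-MCAR" if bool(sig.any()) else "consistent-with-MCAR"

    def write(self, path, sep: str = "\t") -> None:
        self.tests.to_csv(path, sep=sep, index=False)


def _adjust(p: pd.Series, rule: str) -> pd.Series:
    pv = p.to_numpy(dtype=float)
    if rule == "none":
        return p
    k = np.isfinite(pv).sum()
    if rule == "bonferroni":
        return pd.Series(np.minimum(pv * k, 1.0), index=p.index)
    if rule == "holm":
        order = np.argsort(np.where(np.isfinite(pv), pv, np.inf))
        adj = np.full_like(pv, np.nan)
        running = 0.0
        rank = 0
        for i in order:
            if not np.isfinite(pv[i]):
                continue
            cand = (k - rank) * pv[i]
            running = max(running, cand)
            adj[i] = min(running, 1.0)
            rank += 1
        return pd.Series(adj, index=p.index)
    raise ValueError(f"unknown multiplicity rule {rule!r}")


def _fisher_montecarlo(table: np.ndarray, rng: np.random.Generator, n_sim: int = 2000) -> float:
    """Monte-Carlo permutation p-value for an r x c contingency table,
    using the chi-square statistic on label permutations."""
    groups = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    labels = np.concatenate([
        np.repeat(np.arange(table.shape[1]), row) for row in table
    ])

    def chi2_stat(tab):
        exp = tab.sum(axis=1, keepdims=True) * tab.sum(axis=0, keepdims=True) / tab.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(exp > 0, (tab - exp) ** 2 / exp, 0.0)
        return terms.sum()

    obs = chi2_stat(table.astype(float))
    hits = 0
    for _ in range(n_sim):
        perm = rng.permutation(labels)
        tab = np.zeros_like(table, dtype=float)
        np.add.at(tab, (groups, perm), 1.0)
        if chi2_stat(tab) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_sim + 1)


def dixon_battery(
    cohort: Cohort | pd.DataFrame,
    target: str,
    companions: list[str],
    alpha: float = 0.05,
    multiplicity: str = "bonferroni",
    seed: int = 0,
) -> MissingnessTestReport:
    """Per-variable missingness screening against a set of companions."""
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    miss = df[target].isna()
    if not miss.any() or miss.all():
        raise ValueError(f"target {target!r} needs both missing and observed values")
    rng = np.random.default_rng(seed)
    rows = []
    for comp in companions:
        vals = df[comp]
        note = ""
        if vals.dropna().nunique() <= 1:
            rows.append((comp, "skipped", np.nan, np.nan, "constant companion"))
            continue
        if comp in CONTINUOUS_COMPANIONS or (
            comp not in _CAT_LEVELS and pd.api.types.is_numeric_dtype(vals) and vals.dropna().nunique() > 2
        ):
            a = pd.to_numeric(vals[miss], errors="coerce").dropna()
            b = pd.to_numeric(vals[~miss], errors="coerce").dropna()
            if len(a) == 0 or len(b) == 0:
                rows.append((comp, "skipped", np.nan, np.nan, "empty group"))
                continue
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append((comp, "mann-whitney", float(stat), float(p), note))
        else:
            sub = pd.DataFrame({"miss": miss, "val": vals}).dropna(subset=["val"])
            table = pd.crosstab(sub["miss"], sub["val"]).to_numpy()
            if table.shape[0] < 2 or table.shape[1] < 2:
                rows.append((comp, "skipped", np.nan, np.nan, "single observed group"))
                continue
            if table.shape == (2, 2):
                stat, p = stats.fisher_exact(table)
                rows.append((comp, "fisher-exact", float(stat), float(p), note))
            else:
                p = _fisher_montecarlo(table, rng)
                rows.append((comp, "fisher-montecarlo", np.nan, float(p), note))
    tests = pd.DataFrame(rows, columns=["companion", "test", "statistic", "p_value", "note"])
    tests["p_adjusted"] = _adjust(tests["p_value"], multiplicity)
    return MissingnessTestReport(target=target, tests=tests, alpha=alpha, multiplicity=multiplicity)


def baseline_by_missingness(
    cohort: Cohort | pd.DataFrame, target: str, covariates: list[str]
) -> pd.DataFrame:
    """Stratified baseline table: counts and percentages of each covariate
    among target-observed, target-missing and all subjects, with a
    chi-square p-value per covariate."""
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    miss = df[target].isna()
    rows = []
    for cov in covariates:
        vals = df[cov].astype(object).where(df[cov].notna(), "Missing")
        levels = [lev for lev in vals.unique()]
        tab = pd.crosstab(vals, miss)
        tab = tab.reindex(columns=[False, True], fill_value=0)
        counts = tab.to_numpy().T  # rows: observed, missing
        keep = counts.sum(axis=0) > 0
        if keep.sum() >= 2 and counts.sum(axis=1).min() > 0:
            _, p, _, _ = stats.chi2_contingency(counts[:, keep])
        else:
            p = np.nan
        n_obs, n_mis = (~miss).sum(), miss.sum()
        for lev in tab.index:
            o, mcount = int(tab.loc[lev, False]), int(tab.loc[lev, True])
            rows.append((
                cov, lev, o, float(round_half_up(100 * o / max(n_obs, 1), 1)),
                mcount, float(round_half_up(100 * mcount / max(n_mis, 1), 1)),
                o + mcount, float(round_half_up(100 * (o + mcount) / len(df), 1)),
                float(p) if np.isfinite(p) else np.nan,
            ))
    return pd.DataFrame(rows, columns=[
        "covariate", "level", "n_observed", "pct_observed",
        "n_missing", "pct_missing", "n_total", "pct_total", "chi2_p",
    ])
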