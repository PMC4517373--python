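"""Nonparametric survival estimators on a single completed cohort.

Three estimators share the :class:`SurvivalCurve` container:

* overall / cause-specific Kaplan-Meier (other-cause deaths censored),
  with Greenwood pointwise variance;
* the Aalen-Johansen cumulative incidence for competing risks, with the
  Aalen/Dinse-Larson pointwise variance;
* the Pohar-Perme net-survival estimator, which weights each subject's
  at-risk and event contributions by the inverse of their expected
  (population) survival taken from a life table.

All times are in days internally; conversion to years (365.25 d/y) is a
reporting concern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

CURVE_KINDS = ("overall-km", "cause-specific-km", "cif-complement", "net-pp")


@dataclass
class SurvivalCurve:
    """Right-continuous step function of time with pointwise variances.

    ``estimate[j]`` is the value of the curve on ``[times[j], times[j+1])``;
    before ``times[0]`` the curve is 1 with zero variance.  Values may
    exceed 1 only for ``kind='net-pp'``.
    """

    times: np.ndarray
    estimate: np.ndarray
    variance: np.ndarray
    at_risk: np.ndarray | None = None
    events: np.ndarray | None = None
    kind: str = "overall-km"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.estimate.shape != self.times.shape or self.variance.shape != self.times.shape:
            raise ValueError("estimate/variance must align with times")
        if np.any(self.variance < 0):
            raise ValueError("variance must be nonnegative")
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}")

    def evaluate(self, t) -> np.ndarray:
        """Right-continuous (last-value-carried-forward) evaluation; 1 before the first step."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.estimate[np.clip(idx, 0, None)], 1.0)
        return out

    def variance_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.variance[np.clip(idx, 0, None)], 0.0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time": self.times, "estimate": self.estimate, "variance": self.variance}
        )
        if self.at_risk is not None:
            df["n_risk"] = self.at_risk
        if self.events is not None:
            df["n_event"] = self.events
        return df

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Life tables


@dataclass
class LifeTable:
    """Population mortality rates indexed by sex, integer attained age and calendar year.

    Rates are stored per person-year; lookups outside the covered
    age/year rectangle clamp to the nearest cell (with a warning).
    """

    ages: np.ndarray
    years: np.ndarray
    rates: dict[str, np.ndarray] = field(default_factory=dict)  # sex -> (n_age, n_year)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        for sex, mat in self.rates.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (self.ages.size, self.years.size):
                raise ValueError(f"rate matrix for {sex!r} has wrong shape")
            if np.any(mat < 0):
                raise ValueError("life-table hazard rates must be nonnegative")
            self.rates[sex] = mat

    def annual_rate(self, sex: str, age, year) -> np.ndarray:
        """Clamped lookup of the expected mortality rate (per person-year)."""
        age = np.atleast_1d(np.asarray(age))
        year = np.atleast_1d(np.asarray(year))
        if np.any(age < self.ages[0]) or np.any(age > self.ages[-1]) or np.any(
            year < self.years[0]
        ) or np.any(year > self.years[-1]):
            warnings.warn("life-table lookup outside coverage; clamping to nearest cell")
        ai = np.clip(np.searchsorted(self.ages, age, side="right") - 1, 0, self.ages.size - 1)
        yi = np.clip(np.searchsorted(self.years, year, side="right") - 1, 0, self.years.size - 1)
        return self.rates[sex][ai, yi]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex, mat in self.rates.items():
            for i, a in enumerate(self.ages):
                for j, y in enumerate(self.years):
                    rows.append((sex, int(a), int(y), mat[i, j]))
        return pd.DataFrame(rows, columns=["sex", "age", "year", "rate"])

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        ages = np.sort(df["age"].unique())
        years = np.sort(df["year"].unique())
        rates = {}
        for sex, sub in df.groupby("sex"):
            piv = sub.pivot_table(index="age", columns="year", values="rate")
            piv = piv.reindex(index=ages, columns=years)
            if piv.isna().any().any():
                raise ValueError("life table is not a complete age x year grid")
            rates[str(sex)] = piv.to_numpy(dtype=float)
        return cls(ages=ages, years=years, rates=rates)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "LifeTable":
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def cumhaz_path(self, sex: str, age0: float, year0: float, grid_days: np.ndarray) -> np.ndarray:
        """Cumulative expected hazard of one subject at each follow-up time in ``grid_days``.

        The hazard is piecewise constant over 1-year age x 1-year period
        cells, and the subject ages along the diagonal: attained age and
        calendar time advance together with follow-up.
        """
        grid_days = np.asarray(grid_days, dtype=float)
        horizon = float(grid_days[-1]) if grid_days.size else 0.0
        # breakpoints (in days of follow-up) where the integer age or year changes
        bps = {0.0, horizon}
        for start in (age0, year0):
            k = np.floor(start) + 1.0
            while (k - start) * DAYS_PER_YEAR < horizon:
                bps.add((k - start) * DAYS_PER_YEAR)
                k += 1.0
        bp = np.array(sorted(bps))
        mid = (bp[:-1] + bp[1:]) / 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # clamping warning handled by caller
            seg_rate = self.annual_rate(
                sex, np.floor(age0 + mid / DAYS_PER_YEAR), np.floor(year0 + mid / DAYS_PER_YEAR)
            )
        seg_ch = np.concatenate([[0.0], np.cumsum(seg_rate / DAYS_PER_YEAR * np.diff(bp))])
        return np.interp(grid_days, bp, seg_ch)


# ---------------------------------------------------------------------------
# Kaplan-Meier


def _as_time_event(times, event):
    t = np.asarray(times, dtype=float)
    e = np.asarray(event).astype(int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and event must be 1-D and aligned")
    if np.any(t < 1):
        raise ValueError("follow-up times must be >= 1 day")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event must be binary")
    return t, e


def kaplan_meier(times, event, kind: str = "overall-km") -> SurvivalCurve:
    """Product-limit estimate with Greenwood variance.

    The curve is evaluated at the distinct event times.  Censorings tied
    with an event time are handled after the events at that time (the
    censored subject is still at risk at that time).
    """
    t, e = _as_time_event(times, event)
    if e.sum() == 0:
        last = t.max() if t.size else 1.0
        return SurvivalCurve(
            times=np.array([last]), estimate=np.array([1.0]), variance=np.array([0.0]),
            at_risk=np.array([t.size]), events=np.array([0]), kind=kind,
        )
    grid = np.unique(t[e == 1])
    n_risk = (t[None, :] >= grid[:, None]).sum(axis=1)
    d = np.array([(e[t == g] == 1).sum() for g in grid])
    s = np.cumprod(1.0 - d / n_risk)
    # Greenwood: S(t)^2 * sum d/(n(n-d)); the n==d term drives S to 0, variance 0 there
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_risk > d, d / (n_risk * (n_risk - d).astype(float)), 0.0)
    var = s**2 * np.cumsum(terms)
    return SurvivalCurve(times=grid, estimate=s, variance=var, at_risk=n_risk, events=d, kind=kind)


def cause_specific_km(times, dead, cause, cause_of_interest: str = "prostate") -> SurvivalCurve:
    """Kaplan-Meier treating only deaths from ``cause_of_interest`` as events.

    Deaths from other causes are censored at their death time; requires a
    completed cohort (no dead subject may have a missing cause).
    """
    t = np.asarray(times, dtype=float)
    dead = np.asarray(dead).astype(int)
    cause = np.asarray(cause, dtype=object)
    missing = (dead == 1) & pd.isna(cause)
    if missing.any():
        raise ValueError(
            f"{missing.sum()} deceased subjects have a missing cause of death; impute first"
        )
    event = ((dead == 1) & (cause == cause_of_interest)).astype(int)
    return kaplan_meier(t, event, kind="cause-specific-km")


# ---------------------------------------------------------------------------
# Aalen-Johansen cumulative incidence


@dataclass
class CompetingRisksResult:
    """Aalen-Johansen estimates: per-cause CIFs plus the overall survival.

    ``survival_complement(cause)`` returns 1 - CIF_cause as a
    :class:`SurvivalCurve` (the "competing-risks survival" for that cause).
    """

    times: np.ndarray
    overall_survival: np.ndarray
    cif: dict[str, np.ndarray]
    cif_variance: dict[str, np.ndarray]
    at_risk: np.ndarray
    events: dict[str, np.ndarray]

    def survival_complement(self, cause: str = "prostate") -> SurvivalCurve:
        return SurvivalCurve(
            times=self.times,
            estimate=1.0 - self.cif[cause],
            variance=self.cif_variance[cause],
            at_risk=self.at_risk,
            events=self.events[cause],
            kind="cif-complement",
        )


def cumulative_incidence(times, dead, cause) -> CompetingRisksResult:
    """Aalen-Johansen estimator of the cause-specific cumulative incidence.

    ``CIF_k(t) = sum_{s<=t} S(s-) d_k(s)/n(s)`` with ``S`` the overall
    Kaplan-Meier; pointwise variance by the Aalen/Dinse-Larson
    delta-method form.  Satisfies ``S(t) + sum_k CIF_k(t) = 1`` at every
    event time.
    """
    t = np.asarray(times, dtype=float)
    dead = np.asarray(dead).astype(int)
    cause = np.asarray(cause, dtype=object)
    missing = (dead == 1) & pd.isna(cause)
    if missing.any():
        raise ValueError(
            f"{missing.sum()} deceased subjects have a missing cause of death; impute first"
        )
    causes = sorted({str(c) for c, d in zip(cause, dead) if d == 1})
    grid = np.unique(t[dead == 1])
    if grid.size == 0:
        raise ValueError("no events: cumulative incidence undefined")
    n_risk = (t[None, :] >= grid[:, None]).sum(axis=1)
    d_tot = np.array([((t == g) & (dead == 1)).sum() for g in grid])
    d_k = {
        k: np.array([((t == g) & (dead == 1) & (cause == k)).sum() for g in grid]) for k in causes
    }
    s = np.cumprod(1.0 - d_tot / n_risk)
    s_minus = np.concatenate([[1.0], s[:-1]])  # S(t_j-)
    cif = {k: np.cumsum(s_minus * d_k[k] / n_risk) for k in causes}

    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.where(n_risk > d_tot, d_tot / (n_risk * (n_risk - d_tot).astype(float)), 0.0)
    var = {}
    for k in causes:
        dk = d_k[k]
        a = np.cumsum(gw)                       # sum d/(n(n-d))
        b = np.cumsum(cif[k] * gw)              # sum F_k(t_j) d/(n(n-d))
        c = np.cumsum(cif[k] ** 2 * gw)
        term2 = np.cumsum(s_minus**2 * (n_risk - dk) / n_risk * dk / n_risk**2)
        e1 = np.cumsum(s_minus * dk / n_risk**2)
        e2 = np.cumsum(cif[k] * s_minus * dk / n_risk**2)
        Ft = cif[k]
        v = (Ft**2 * a - 2 * Ft * b + c) + term2 - 2 * (Ft * e1 - e2)
        var[k] = np.maximum(v, 0.0)
    return CompetingRisksResult(
        times=grid, overall_survival=s, cif=cif, cif_variance=var, at_risk=n_risk, events=d_k
    )


# ---------------------------------------------------------------------------
# Pohar-Perme net survival


def pohar_perme(times, dead, age_at_diagnosis, diagnosis_year, sex, life_table: LifeTable):
    """Pohar-Perme net-survival estimator.

    Each subject's at-risk and event contributions at follow-up time ``t``
    are weighted by ``1/S_pop_i(t)``, the inverse of their expected
    survival from the life table.  Net survival is
    ``exp(-cumulative excess hazard)`` and may exceed 1 when the cohort
    dies less than the general population predicts.  Variance is the
    Poisson-type estimator ``sum w_i^2 dN_i / (sum w Y)^2`` on the
    hazard scale, delta-transformed to the survival scale.

    The population-hazard term is integrated exactly under the life
    table's piecewise-constant hazard, using
    ``int_a^b w_i dLambda_pop_i = w_i(b) - w_i(a)``.
    """
    t = np.asarray(times, dtype=float)
    dead = np.asarray(dead).astype(int)
    age0 = np.asarray(age_at_diagnosis, dtype=float)
    year0 = np.asarray(diagnosis_year, dtype=float)
    if isinstance(sex, str):
        sex = np.full(t.size, sex, dtype=object)
    sex = np.asarray(sex, dtype=object)
    n = t.size

    grid = np.unique(t)  # all exit times: the risk set is constant between them
    # cumulative expected hazard of each subject at each grid time (capped at exit)
    H = np.empty((n, grid.size))
    for i in range(n):
        H[i] = life_table.cumhaz_path(sex[i], age0[i], year0[i], np.minimum(grid, t[i]))
    W = np.exp(H)  # w_i(t) = 1/S_pop_i(t)

    at_risk_mask = t[None, :] >= grid[:, None]            # (G, n)
    W_prev = np.concatenate([np.ones((n, 1)), W[:, :-1]], axis=1)
    denom = (at_risk_mask * W.T).sum(axis=1)
    pop_term = (at_risk_mask * (W - W_prev).T).sum(axis=1)
    is_death = dead == 1
    death_w = np.zeros(grid.size)
    death_w2 = np.zeros(grid.size)
    gi = np.searchsorted(grid, t)
    for i in np.nonzero(is_death)[0]:
        death_w[gi[i]] += W[i, gi[i]]
        death_w2[gi[i]] += W[i, gi[i]] ** 2

    with np.errstate(divide="ignore", invalid="ignore"):
        d_lambda_e = np.where(denom > 0, (death_w - pop_term) / denom, 0.0)
        d_var = np.where(denom > 0, death_w2 / denom**2, 0.0)
    lam = np.cumsum(d_lambda_e)
    var_lam = np.cumsum(d_var)
    net = np.exp(-lam)
    var_net = net**2 * var_lam

    keep = np.array([((t == g) & is_death).any() for g in grid])
    n_risk = at_risk_mask.sum(axis=1)
    d_count = np.array([((t == g) & is_death).sum() for g in grid])
    if not keep.any():
        keep = np.zeros(grid.size, dtype=bool)
        keep[-1] = True
    return SurvivalCurve(
        times=grid[keep],
        estimate=net[keep],
        variance=var_net[keep],
        at_risk=n_risk[keep],
        events=d_count[keep],
        kind="net-pp",
    )


def nelson_aalen_survival(times, event) -> SurvivalCurve:
    """exp(-Nelson-Aalen) of overall mortality (used as the zero-population-hazard limit)."""
    t, e = _as_time_event(times, event)
    grid = np.unique(t[e == 1])
    n_risk = (t[None, :] >= grid[:, None]).sum(axis=1)
    d = np.array([(e[t == g] == 1).sum() for g in grid])
    lam = np.cumsum(d / n_risk)
    s = np.exp(-lam)
    var = s**2 * np.cumsum(d / n_risk.astype(float) ** 2)
    return SurvivalCurve(times=grid, estimate=s, variance=var, at_risk=n_risk, events=d, kind="net-pp")
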