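"""Synthetic cohorts with known ground truth.

The generator emulates a screening-cohort of men diagnosed with prostate
cancer: ages 56-78 at diagnosis, diagnosis years 2003-2011,
administrative censoring mid-2013 (about a 10-year horizon), roughly
11% deceased, and a 1:2 prostate:other cause split among deaths, with
about half of the causes of death maskable under a configurable
missingness mechanism.  Covariates share a latent severity factor so
they carry real information about the cause of death, which is what the
imputation model must exploit.

Event times follow cause-specific proportional hazards with closed-form
cumulative hazards (Weibull baseline for prostate-cancer death,
Gompertz-in-attained-age for other causes), so the exact generating
cause-specific survival is available at any time.  The default
other-cause level sits *below* the bundled population life-table preset
— the healthy-volunteer effect of screening trials — which is what makes
net survival exceed 100% early on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    CT_LEVELS, PT_LEVELS, TREATMENT_LEVELS, GLEASON_LEVELS, Cohort,
)
from .estimators import DAYS_PER_YEAR, LifeTable

#: default per-variable covariate missingness rates (MCAR), loosely
#: following registry practice: imaging-based stages and post-treatment
#: PSA are the patchiest
DEFAULT_COVARIATE_MISSING = {
    "psa_diag": 0.062, "cT": 0.207, "cN": 0.038, "cM": 0.136,
    "first_treatment": 0.003, "gleason_group": 0.046, "psa_post": 0.271,
    "pT": 0.06, "pN": 0.395,
}

_CT_BASE = np.array([0.02, 0.03, 0.58, 0.11, 0.06, 0.09, 0.06, 0.03, 0.02])
_PT_BASE = np.array([0.20, 0.21, 0.43, 0.10, 0.04, 0.02])
_TREAT_BASE = np.array([0.59, 0.18, 0.18, 0.05])  # surgery, radio, horm+chemo, surv+HIFU


@dataclass
class GeneratorConfig:
    n: int = 2844
    seed: int = 0
    age_low: float = 56.0
    age_high: float = 78.0
    age_mean: float = 67.0
    age_sd: float = 5.5
    year_low: int = 2003
    year_high: int = 2011
    end_of_study: float = 2013.5
    # prostate-cancer death: Weibull(k) baseline with log-linear severity effect
    prostate_log_rate: float = -6.7
    prostate_shape: float = 1.6
    prostate_beta_z: float = 0.9
    # other-cause death: Gompertz in attained age with a mild frailty
    other_gompertz_a: float = 2.2e-5
    other_gompertz_b: float = 0.091
    other_beta_z: float = 0.3
    # loss to follow-up (exponential, per year)
    dropout_rate: float = 0.01
    # missingness of the cause of death
    mechanism: str = "MAR"           # MCAR | MAR | MNAR
    missing_fraction: float = 0.5
    exact_count: bool = False
    mar_year_slope: float = 1.4      # MAR: log-odds of masking per year since 2008
    mnar_cause_shift: float = 2.0    # MNAR: extra log-odds of masking for prostate deaths
    covariate_missing: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_MISSING))

    def validate(self) -> None:
        if not (0.0 <= self.missing_fraction <= 1.0):
            raise ValueError("missing_fraction must lie in [0, 1]")
        if self.prostate_shape <= 0 or self.other_gompertz_a < 0 or self.other_gompertz_b <= 0:
            raise ValueError("hazard parameters must be positive")
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise ValueError(f"unknown missingness mechanism {self.mechanism!r}")


@dataclass
class CohortTruth:
    """Everything the generator knows and the analyst normally does not."""

    true_cause: pd.Series          # cause for every deceased subject (never missing)
    severity: np.ndarray           # latent severity factor z
    prostate_rates: np.ndarray     # per-subject Weibull rate multiplier (per year^k)
    prostate_shape: float
    other_params: tuple            # (a, b, per-subject frailty)
    ages: np.ndarray

    def analytic_survival(self, t_days) -> np.ndarray:
        """Exact generating cause-specific (net) survival, marginal over the
        realized covariates: mean_i exp(-Lambda_prostate_i(t))."""
        t = np.atleast_1d(np.asarray(t_days, dtype=float)) / DAYS_PER_YEAR
        lam = self.prostate_rates[:, None] * t[None, :] ** self.prostate_shape
        return np.exp(-lam).mean(axis=0)


def _truncnorm(rng, lo, hi, mu, sd, size):
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.normal(mu, sd, size=int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.nonzero(need)[0][ok]
        out[idx] = draw[ok]
        need[idx] = False
    return out


def _tilted_categorical(rng, base_probs, z, tilt, labels):
    ranks = np.arange(len(base_probs)) - (len(base_probs) - 1) / 2.0
    logits = np.log(base_probs)[None, :] + tilt * z[:, None] * ranks[None, :]
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(z.size)
    picks = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    return np.array([labels[k] for k in picks], dtype=object)


def generate_cohort(config: GeneratorConfig | None = None) -> tuple[Cohort, CohortTruth]:
    """Draw a cohort plus its ground truth; seed-deterministic."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    age = _truncnorm(rng, cfg.age_low, cfg.age_high, cfg.age_mean, cfg.age_sd, n)
    year = rng.integers(cfg.year_low, cfg.year_high + 1, size=n)
    entry_frac = rng.random(n)  # position of diagnosis within the year
    z = rng.normal(0.0, 1.0, size=n)

    psa_diag = np.exp(np.log(7.0) + 0.55 * z + 0.35 * rng.normal(size=n))
    g_star = z + 0.8 * rng.normal(size=n)
    gleason = np.select(
        [g_star <= 0.03, g_star <= 1.80], [GLEASON_LEVELS[0], GLEASON_LEVELS[1]],
        GLEASON_LEVELS[2],
    ).astype(object)
    cT = _tilted_categorical(rng, _CT_BASE, z, 0.25, CT_LEVELS)
    cN = (rng.random(n) < 1.0 / (1.0 + np.exp(-(-4.3 + 0.8 * z)))).astype(int)
    cM = (rng.random(n) < 1.0 / (1.0 + np.exp(-(-4.0 + 0.9 * z)))).astype(int)

    treat_logits = np.log(_TREAT_BASE)[None, :].repeat(n, axis=0)
    treat_logits[:, 0] += -0.06 * (age - 67.0)           # surgery less likely when older
    treat_logits[:, 2] += 0.05 * (age - 67.0) + 0.3 * z  # hormone+chemo when older/severe
    p = np.exp(treat_logits - treat_logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    labels = [TREATMENT_LEVELS[0], TREATMENT_LEVELS[1], TREATMENT_LEVELS[2], TREATMENT_LEVELS[3]]
    u = rng.random(n)
    treat = np.array([labels[k] for k in (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)],
                     dtype=object)

    surgery = treat == "surgery"
    pT = np.full(n, np.nan, dtype=object)
    pN = np.full(n, np.nan)
    pT[surgery] = _tilted_categorical(rng, _PT_BASE, z[surgery], 0.3, PT_LEVELS)
    pN[surgery] = (rng.random(int(surgery.sum())) <
                   1.0 / (1.0 + np.exp(-(-4.0 + 1.0 * z[surgery])))).astype(int)

    curative = surgery | (treat == "radiotherapy")
    psa_post = np.where(
        curative,
        np.exp(np.log(0.03) + 1.2 * rng.normal(size=n)),
        np.exp(np.log(1.5) + 1.0 * rng.normal(size=n) + 0.3 * z),
    )

    # latent cause-specific event times (years since diagnosis)
    prostate_rate = np.exp(cfg.prostate_log_rate + cfg.prostate_beta_z * z)
    u1 = rng.random(n)
    t_prostate = (-np.log(u1) / prostate_rate) ** (1.0 / cfg.prostate_shape)
    frailty = np.exp(cfg.other_beta_z * z)
    a, b = cfg.other_gompertz_a, cfg.other_gompertz_b
    u2 = rng.random(n)
    with np.errstate(divide="ignore"):  # zero hazard -> infinite latent time
        t_other = np.log(np.exp(b * age) + b * (-np.log(u2)) / (a * frailty)) / b - age

    t_admin = np.maximum(cfg.end_of_study - (year + entry_frac), 1.0 / DAYS_PER_YEAR)
    t_drop = rng.exponential(1.0 / cfg.dropout_rate, size=n) if cfg.dropout_rate > 0 else np.full(n, np.inf)
    t_cens = np.minimum(t_admin, t_drop)
    t_event = np.minimum(t_prostate, t_other)
    dead = (t_event <= t_cens).astype(int)
    followup = np.maximum(np.ceil(np.minimum(t_event, t_cens) * DAYS_PER_YEAR), 1).astype(int)
    which = np.where(t_prostate <= t_other, "prostate", "other").astype(object)
    cause = pd.Series([which[i] if dead[i] else np.nan for i in range(n)], dtype=object)

    df = pd.DataFrame({
        "id": [f"P{i:05d}" for i in range(n)],
        "age_at_diagnosis": age,
        "psa_diag": psa_diag,
        "cT": cT, "cN": cN.astype(float), "cM": cM.astype(float),
        "first_treatment": treat,
        "gleason_group": gleason,
        "pT": pT, "pN": pN,
        "psa_post": psa_post,
        "followup_days": followup,
        "dead": dead,
        "cause": cause,
        "sex": "male",
        "diagnosis_year": year,
    })

    # covariate missingness (MCAR per variable); pT/pN only within surgery
    for var, rate in cfg.covariate_missing.items():
        if rate <= 0:
            continue
        eligible = surgery if var in ("pT", "pN") else np.ones(n, dtype=bool)
        mask = eligible & (rng.random(n) < rate)
        df.loc[mask, var] = np.nan
        if var == "first_treatment":
            # a record without a recorded treatment cannot carry a linked
            # pathology report either (keeps the surgery invariant)
            df.loc[mask, ["pT", "pN"]] = np.nan

    truth = CohortTruth(
        true_cause=cause.copy(), severity=z, prostate_rates=prostate_rate,
        prostate_shape=cfg.prostate_shape, other_params=(a, b, frailty), ages=age,
    )
    full = Cohort(df, provenance=f"synthetic(seed={cfg.seed}, n={n})")
    masked = mar_mechanism(full, truth, cfg.mechanism, cfg.missing_fraction,
                           seed=int(rng.integers(2**31)), exact_count=cfg.exact_count,
                           mar_year_slope=cfg.mar_year_slope,
                           mnar_cause_shift=cfg.mnar_cause_shift)
    return masked, truth


def mar_mechanism(
    cohort: Cohort,
    truth: CohortTruth | None,
    mechanism: str = "MAR",
    fraction: float = 0.5,
    seed: int = 0,
    exact_count: bool = False,
    mar_year_slope: float = 1.4,
    mnar_cause_shift: float = 2.0,
) -> Cohort:
    """Mask causes of death among the deceased.

    MCAR masks uniformly; MAR makes the masking log-odds increase with
    diagnosis year (late-diagnosed deaths lack a cause, emulating a
    registry whose cause request lags the calendar); MNAR shifts the
    masking log-odds by the true cause itself.  The achieved fraction is
    calibrated to the target (exactly, under ``exact_count``).
    """
    if fraction <= 0:
        return cohort.copy()
    df = cohort.data.copy()
    dead_idx = df.index[df["dead"] == 1]
    n_dead = len(dead_idx)
    if n_dead == 0:
        return cohort.copy()
    k_target = fraction * n_dead
    if exact_count and round(k_target) > n_dead:
        raise ValueError("cannot mask more causes than there are deaths")
    rng = np.random.default_rng(seed)
    if mechanism == "MCAR":
        score = np.zeros(n_dead)
    elif mechanism == "MAR":
        score = mar_year_slope * (df.loc[dead_idx, "diagnosis_year"].to_numpy(float) - 2008.0)
    elif mechanism == "MNAR":
        if truth is None:
            raise ValueError("MNAR masking needs the truth object")
        score = mnar_cause_shift * (truth.true_cause.loc[dead_idx] == "prostate").to_numpy(float)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")

    if exact_count:
        k = int(round(k_target))
        w = np.exp(score - score.max())
        chosen = rng.choice(dead_idx, size=k, replace=False, p=w / w.sum())
    else:
        # calibrate the intercept so the mean masking probability hits the target
        lo, hi = -30.0, 30.0
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if np.mean(1.0 / (1.0 + np.exp(-(mid + score)))) < fraction:
                lo = mid
            else:
                hi = mid
        p = 1.0 / (1.0 + np.exp(-((lo + hi) / 2.0 + score)))
        chosen = dead_idx[rng.random(n_dead) < p]
    df.loc[chosen, "cause"] = np.nan
    return Cohort(df, provenance=cohort.provenance + f" | masked({mechanism}, {fraction})",
                  n_excluded_zero_followup=cohort.n_excluded_zero_followup)


def generate_life_table(
    preset: str = "gompertz-male",
    ages=range(50, 101),
    years=range(2000, 2021),
    base_hazard_fn=None,
    gompertz_a: float = 3.2e-5,
    gompertz_b: float = 0.091,
) -> LifeTable:
    """Tabulate a population life table on an age x year grid.

    Presets: ``zero`` (all rates 0 — the Nelson-Aalen limit of the net
    estimator) and ``gompertz-male`` (exponentially increasing male
    mortality).  ``base_hazard_fn(age, year)`` overrides both.
    """
    ages = np.asarray(list(ages), dtype=int)
    years = np.asarray(list(years), dtype=int)
    A, Y = np.meshgrid(ages, years, indexing="ij")
    if base_hazard_fn is not None:
        rates = np.vectorize(base_hazard_fn)(A, Y).astype(float)
    elif preset == "zero":
        rates = np.zeros_like(A, dtype=float)
    elif preset == "gompertz-male":
        rates = gompertz_a * np.exp(gompertz_b * A.astype(float))
    else:
        raise ValueError(f"unknown preset {preset!r}")
    if np.any(rates < 0):
        raise ValueError("life-table hazard rates must be nonnegative")
    return LifeTable(ages=ages, years=years, rates={"male": rates})
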