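"""Multiple imputation by chained equations (fully conditional specification).

The engine iterates variable-by-variable conditional imputation over a
clinically ordered visit sequence, with three per-variable model types
(predictive mean matching for continuous, logistic for binary,
multinomial logit for unordered categories), *conditional* imputation
domains (the cause of death exists only for the deceased; pathological
stage only after surgery), *passive* derived variables (T_new, N_new,
d'Amico) recomputed after every sweep, automatic predictor selection in
the style of quickpred, and Gelman-Rubin convergence diagnostics on the
chains of imputed-value means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _glm
from .cohort import (
    CATEGORY_LEVELS,
    DAMICO_LEVELS,
    CT_LEVELS,
    IMPUTABLE_VARIABLES,
    PASSIVE_VARIABLES,
    Cohort,
    derive_covariates,
)

#: order of the variables in the predictor matrix
MATRIX_VARIABLES = [
    "cause", "age_at_diagnosis", "psa_diag", "cT", "cN", "cM", "first_treatment",
    "gleason_group", "pT", "pN", "psa_post", "T_new", "N_new", "damico_group",
]

#: optional survival-model predictors (off by default)
OPTIONAL_PREDICTORS = ["followup_days", "dead", "cumhaz"]

DEFAULT_METHODS = {
    "psa_diag": "pmm",
    "cT": "multinomial",
    "cN": "logistic",
    "cM": "logistic",
    "gleason_group": "multinomial",
    "first_treatment": "multinomial",
    "pT": "multinomial",
    "pN": "logistic",
    "psa_post": "pmm",
    "cause": "logistic",
}

#: clinical chronological visit order
DEFAULT_VISIT_SEQUENCE = [
    "psa_diag", "cT", "cN", "cM", "gleason_group", "first_treatment",
    "pT", "pN", "psa_post", "cause",
]

DOMAINS = {
    "cause": lambda df: df["dead"] == 1,
    "pT": lambda df: df["first_treatment"] == "surgery",
    "pN": lambda df: df["first_treatment"] == "surgery",
}

_CAT_LEVELS = dict(CATEGORY_LEVELS)
_CAT_LEVELS["T_new"] = CT_LEVELS
_CAT_LEVELS["damico_group"] = DAMICO_LEVELS


def domain_mask(var: str, df: pd.DataFrame) -> pd.Series:
    if var in DOMAINS:
        return DOMAINS[var](df).fillna(False).astype(bool)
    return pd.Series(True, index=df.index)


def numeric_code(var: str, values: pd.Series) -> pd.Series:
    """Map a variable to a numeric coding (category -> level index)."""
    if var in _CAT_LEVELS:
        levels = _CAT_LEVELS[var]
        return values.map({lev: float(i) for i, lev in enumerate(levels)})
    return pd.to_numeric(values, errors="coerce")


@dataclass
class ImputationSpec:
    """What to impute, how, in which order, and how many times."""

    methods: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_METHODS))
    visit_sequence: list[str] = field(default_factory=lambda: list(DEFAULT_VISIT_SEQUENCE))
    m: int = 20
    n_iter: int = 20
    seed: int = 0
    pmm_donors: int = 5
    include_optional_predictors: bool = False

    def to_yaml(self, path) -> None:
        import yaml

        payload = {
            "methods": dict(self.methods),
            "visit_sequence": list(self.visit_sequence),
            "m": self.m, "n_iter": self.n_iter, "seed": self.seed,
            "pmm_donors": self.pmm_donors,
            "include_optional_predictors": self.include_optional_predictors,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ImputationSpec":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def validate(self, df: pd.DataFrame) -> None:
        if sorted(set(self.visit_sequence)) != sorted(self.visit_sequence):
            raise ValueError("visit_sequence must list each variable exactly once")
        for var in self.visit_sequence:
            if var not in self.methods:
                raise ValueError(f"no imputation method declared for {var!r}")
            if self.methods[var] not in {"pmm", "logistic", "multinomial", "passive", "none"}:
                raise ValueError(f"unknown method {self.methods[var]!r} for {var!r}")
        for var in self.visit_sequence:
            if var not in df.columns:
                raise ValueError(f"visit_sequence variable {var!r} not in cohort")
        if self.m < 1 or self.n_iter < 1:
            raise ValueError("m and n_iter must be positive")


# ---------------------------------------------------------------------------
# Predictor matrix


def empty_predictor_matrix(variables=None) -> pd.DataFrame:
    variables = list(variables) if variables is not None else list(MATRIX_VARIABLES)
    return pd.DataFrame(0, index=variables, columns=variables, dtype=int)


def validate_predictor_matrix(matrix: pd.DataFrame) -> None:
    if list(matrix.index) != list(matrix.columns):
        raise ValueError("predictor matrix must be square with matching labels")
    if not matrix.isin([0, 1]).all().all():
        raise ValueError("predictor matrix entries must be 0/1")
    if np.any(np.diag(matrix.to_numpy()) != 0):
        raise ValueError("predictor matrix must have a zero diagonal")
    for var in PASSIVE_VARIABLES:
        if var in matrix.index and matrix.loc[var].any():
            raise ValueError(f"passive variable {var!r} must have an all-zero row")


def clinical_predictor_matrix() -> pd.DataFrame:
    """The clinician-validated predictor matrix used as the engine default.

    Rows are imputation targets, columns predictors.  Fully observed
    (age) and passive (T_new, N_new, d'Amico) variables have all-zero
    rows; pathological stage is never used as a predictor.
    """
    rows = {
        "cause":            "01100111001111",
        "age_at_diagnosis": "00000000000000",
        "psa_diag":         "01011101000000",
        "cT":               "01100001000000",
        "cN":               "01110101001101",
        "cM":               "01110001000000",
        "first_treatment":  "01111101000001",
        "gleason_group":    "01101110000100",
        "pT":               "01010110000000",
        "pN":               "01010110000000",
        "psa_post":         "01100110000100",
        "T_new":            "00000000000000",
        "N_new":            "00000000000000",
        "damico_group":     "00000000000000",
    }
    mat = pd.DataFrame(
        [[int(c) for c in rows[v]] for v in MATRIX_VARIABLES],
        index=MATRIX_VARIABLES, columns=MATRIX_VARIABLES, dtype=int,
    )
    validate_predictor_matrix(mat)
    return mat


def quickpred(
    cohort: Cohort | pd.DataFrame,
    min_correlation: float = 0.1,
    min_usable_fraction: float = 0.4,
    variables=None,
) -> pd.DataFrame:
    """Automatic predictor-matrix construction.

    A predictor is retained for a target iff (a) the larger of
    |corr(target values, predictor)| and |corr(target missingness,
    predictor)| — Pearson on numerically coded, pairwise-complete
    values — reaches ``min_correlation``, and (b) the proportion of
    usable cases (target-missing rows where the predictor is observed)
    reaches ``min_usable_fraction``.  Rows of fully observed or passive
    variables are zero.  The result may be edited afterwards (the
    clinician-override hook — see :func:`apply_overrides`).
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    if any(v not in df.columns for v in PASSIVE_VARIABLES):
        df = pd.concat([df, derive_covariates(df)], axis=1)
    variables = list(variables) if variables is not None else [
        v for v in MATRIX_VARIABLES if v in df.columns
    ]
    if len(variables) < 2:
        raise ValueError("quickpred needs at least two variables")
    coded = pd.DataFrame({v: numeric_code(v, df[v]) for v in variables})
    mat = empty_predictor_matrix(variables)
    for target in variables:
        if target in PASSIVE_VARIABLES:
            continue
        miss = coded[target].isna()
        if not miss.any():
            continue  # fully observed: all-zero row
        for pred in variables:
            if pred == target:
                continue
            pv = coded[pred]
            if pv.dropna().nunique() <= 1:
                warnings.warn(f"constant variable {pred!r} excluded as predictor")
                continue
            usable = float(pv[miss].notna().mean()) if miss.any() else 0.0
            both = coded[target].notna() & pv.notna()
            r_val = 0.0
            if both.sum() >= 3 and coded[target][both].nunique() > 1 and pv[both].nunique() > 1:
                r_val = abs(float(np.corrcoef(coded[target][both], pv[both])[0, 1]))
            obs_p = pv.notna()
            r_mis = 0.0
            if obs_p.sum() >= 3 and miss[obs_p].nunique() > 1 and pv[obs_p].nunique() > 1:
                r_mis = abs(float(np.corrcoef(miss[obs_p].astype(float), pv[obs_p])[0, 1]))
            if max(r_val, r_mis) >= min_correlation and usable >= min_usable_fraction:
                mat.loc[target, pred] = 1
    validate_predictor_matrix(mat)
    return mat


def write_predictor_matrix(matrix: pd.DataFrame, path, sep: str = ",") -> None:
    matrix.to_csv(path, sep=sep, index=True)


def read_predictor_matrix(path, sep: str = ",") -> pd.DataFrame:
    mat = pd.read_csv(path, sep=sep, index_col=0)
    validate_predictor_matrix(mat)
    return mat


def apply_overrides(matrix: pd.DataFrame, set_pairs=(), unset_pairs=()) -> pd.DataFrame:
    """Clinician-edit hook: force predictor-matrix entries on or off."""
    out = matrix.copy()
    for target, pred in set_pairs:
        out.loc[target, pred] = 1
    for target, pred in unset_pairs:
        out.loc[target, pred] = 0
    validate_predictor_matrix(out)
    return out


# ---------------------------------------------------------------------------
# Per-variable imputation models


def _encode_predictor(var: str, values: pd.Series) -> pd.DataFrame:
    """Design columns for one predictor; missing values are mean/zero-filled.

    (Structurally undefined cells — e.g. pathological stage outside the
    surgery domain — must not poison the design.)
    """
    if var in _CAT_LEVELS:
        levels = _CAT_LEVELS[var]
        cols = {f"{var}[{lev}]": (values == lev).astype(float) for lev in levels[1:]}
        return pd.DataFrame(cols, index=values.index)
    x = pd.to_numeric(values, errors="coerce")
    if x.isna().any():
        fill = x.mean() if x.notna().any() else 0.0
        x = x.fillna(fill)
    return pd.DataFrame({var: x.astype(float)}, index=values.index)


def build_design(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    parts = [_encode_predictor(p, df[p]) for p in predictors]
    if not parts:
        return np.zeros((len(df), 0))
    return pd.concat(parts, axis=1).to_numpy(dtype=float)


def _drop_constant(X_obs: np.ndarray, X_mis: np.ndarray):
    if X_obs.shape[1] == 0:
        return X_obs, X_mis
    keep = X_obs.std(axis=0) > 0
    return X_obs[:, keep], X_mis[:, keep]


def impute_pmm(y_obs, X_obs, X_mis, donors: int = 5, rng=None):
    """Predictive mean matching: donate an observed value whose predicted
    mean is closest to the missing case's (posterior-drawn) prediction."""
    rng = rng if rng is not None else np.random.default_rng()
    y_obs = np.asarray(y_obs, dtype=float)
    X_obs = np.asarray(X_obs, dtype=float)
    X_mis = np.asarray(X_mis, dtype=float)
    X_obs, X_mis = _drop_constant(X_obs, X_mis)
    n_obs = y_obs.size
    if n_obs <= X_obs.shape[1] + 1:
        warnings.warn("fewer complete cases than predictors; ridge-regularised PMM fit")
    Z_obs, transform = _glm.standardize_design(X_obs)
    Z_mis = transform(X_mis)
    beta_hat, beta_draw, _ = _glm.bayes_linear_draw(Z_obs, y_obs, rng)
    yhat_obs = Z_obs @ beta_hat
    yhat_mis = Z_mis @ beta_draw
    k = min(donors, n_obs)
    out = np.empty(X_mis.shape[0])
    d = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
    idx = np.argpartition(d, k - 1, axis=1)[:, :k]
    pick = rng.integers(0, k, size=X_mis.shape[0])
    out = y_obs[idx[np.arange(X_mis.shape[0]), pick]]
    return out


def impute_logistic(y_obs, X_obs, X_mis, rng=None, levels=None):
    """Bayesian-flavoured logistic imputation: fit, perturb the
    coefficients by a draw from their asymptotic posterior, draw
    Bernoulli outcomes from the perturbed probabilities.

    ``levels`` names the (reference, event) pair; by default the sorted
    observed support is used."""
    rng = rng if rng is not None else np.random.default_rng()
    y = np.asarray(y_obs)
    observed_levels = sorted(set(y.tolist()))
    if len(observed_levels) == 1:
        warnings.warn("single observed class; degenerate logistic imputation")
        return np.full(np.asarray(X_mis).shape[0], observed_levels[0])
    if levels is None:
        if len(observed_levels) != 2:
            raise ValueError("logistic imputation needs a binary variable")
        levels = observed_levels
    lev0, lev1 = levels
    yb = (y == lev1).astype(float)
    X_obs = np.asarray(X_obs, dtype=float)
    X_mis = np.asarray(X_mis, dtype=float)
    X_obs, X_mis = _drop_constant(X_obs, X_mis)
    Z_obs, transform = _glm.standardize_design(X_obs)
    Z_mis = transform(X_mis)
    # weakly-informative Gaussian prior on the standardised design
    # (sd 2.5 per coefficient, sd 10 for the intercept): keeps the
    # posterior draw proper when the domain is small or separated
    ridge = np.full(Z_obs.shape[1], 1.0 / 2.5**2)
    ridge[0] = 1.0 / 10.0**2
    beta, cov = _glm.fit_logistic(Z_obs, yb, ridge=ridge)
    cov = (cov + cov.T) / 2.0
    beta_star = rng.multivariate_normal(beta, cov, method="cholesky")
    p = 1.0 / (1.0 + np.exp(-np.clip(Z_mis @ beta_star, -30, 30)))
    draws = rng.random(Z_mis.shape[0]) < p
    return np.where(draws, lev1, lev0)


def impute_multinomial(y_obs, X_obs, X_mis, rng=None):
    """Multinomial-logit imputation; imputed categories respect the
    observed category support.

    Unlike the binary case, the coefficients are not perturbed: under
    quasi-separation (common on small imputation domains) the
    asymptotic covariance of a multinomial logit degenerates and a
    normal draw produces arbitrary class assignments.  Categories are
    drawn from the fitted class probabilities, mirroring the behaviour
    of the standard chained-equations engines for unordered targets.
    """
    rng = rng if rng is not None else np.random.default_rng()
    y = np.asarray(y_obs, dtype=object)
    support = sorted({str(v) for v in y})
    n_mis = np.asarray(X_mis).shape[0]
    if len(support) == 1:
        warnings.warn("single observed category; degenerate multinomial imputation")
        return np.array([support[0]] * n_mis, dtype=object)
    codes = np.array([support.index(str(v)) for v in y])
    X_obs = np.asarray(X_obs, dtype=float)
    X_mis = np.asarray(X_mis, dtype=float)
    X_obs, X_mis = _drop_constant(X_obs, X_mis)
    Z_obs, transform = _glm.standardize_design(X_obs)
    Z_mis = transform(X_mis)
    K = len(support)
    B, _ = _glm.fit_multinomial(Z_obs, codes, K)
    P = _glm.multinomial_probs(Z_mis, B)
    u = rng.random(n_mis)
    cum = np.cumsum(P, axis=1)
    picks = (u[:, None] > cum).sum(axis=1)
    return np.array([support[k] for k in picks], dtype=object)


# ---------------------------------------------------------------------------
# The chained-equations engine


@dataclass
class ImputationResult:
    """m completed cohorts plus per-variable chain statistics."""

    completed: list[pd.DataFrame]
    chain_means: dict[str, np.ndarray]   # var -> (m, n_iter)
    chain_vars: dict[str, np.ndarray]
    spec: ImputationSpec
    matrix: pd.DataFrame
    originally_missing: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.completed)

    def rhat(self) -> pd.Series:
        return pd.Series(
            {var: rhat(self.chain_means[var]) for var in self.chain_means}, name="rhat"
        )

    def export(self, directory, sep: str = ",") -> list[str]:
        """Write the m completed cohorts as delimited files tagged by index."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, df in enumerate(self.completed, start=1):
            out = df.copy()
            out.insert(0, "imputation", i)
            p = directory / f"imputed_{i:02d}.csv"
            out.to_csv(p, sep=sep, index=False)
            paths.append(str(p))
        return paths


def rhat(chain_matrix: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction on an (m chains x n iterations)
    matrix of per-iteration imputed-value means.

    Zero within-chain variance returns 1.0 by convention (with a warning).
    """
    psi = np.asarray(chain_matrix, dtype=float)
    psi = psi[:, ~np.isnan(psi).any(axis=0)]
    m, n = psi.shape
    if m < 2 or n < 2:
        raise ValueError("rhat needs >= 2 chains and >= 2 retained iterations")
    chain_means = psi.mean(axis=1)
    W = psi.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W <= 0:
        if B > 0:
            warnings.warn("zero within-chain variance with nonzero between-chain variance")
            return np.inf
        warnings.warn("zero within-chain variance; rhat = 1 by convention")
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _initialize(df: pd.DataFrame, orig_missing: dict[str, pd.Series],
                spec: ImputationSpec, rng) -> None:
    for var in spec.visit_sequence:
        dom = domain_mask(var, df)
        fill = orig_missing[var] & dom
        obs_vals = df.loc[~orig_missing[var] & dom, var].dropna().to_numpy()
        if fill.any() and obs_vals.size:
            df.loc[fill, var] = rng.choice(obs_vals, size=int(fill.sum()), replace=True)


def run_chained_equations(
    cohort: Cohort,
    spec: ImputationSpec | None = None,
    matrix: pd.DataFrame | None = None,
) -> ImputationResult:
    """Run m seeded FCS chains of ``n_iter`` sweeps each.

    Missing cells are initialised by random draws from the observed
    marginal (within the variable's domain); each sweep re-imputes one
    variable from its current predictors in the visit order; the passive
    variables are recomputed after the sweep; domain-restricted
    variables stay undefined outside their domain.  Observed values are
    never altered.  Identical inputs and seed give identical output.
    """
    spec = spec or ImputationSpec()
    base = cohort.with_derived().data
    spec.validate(base)
    if matrix is None:
        matrix = clinical_predictor_matrix()
    validate_predictor_matrix(matrix)
    if spec.include_optional_predictors and "cumhaz" not in base.columns:
        base = base.assign(cumhaz=_nelson_aalen_cumhaz(base))

    orig_missing = {var: base[var].isna() for var in spec.visit_sequence}
    imputed_vars = [
        v for v in spec.visit_sequence
        if orig_missing[v].any() and spec.methods[v] not in ("none", "passive")
    ]

    completed: list[pd.DataFrame] = []
    chain_means = {v: np.full((spec.m, spec.n_iter), np.nan) for v in imputed_vars}
    chain_vars = {v: np.full((spec.m, spec.n_iter), np.nan) for v in imputed_vars}

    for chain in range(spec.m):
        rng = np.random.default_rng([spec.seed, chain])
        df = base.copy()
        _initialize(df, orig_missing, spec, rng)
        _update_passive(df)
        for it in range(spec.n_iter):
            for var in spec.visit_sequence:
                if var not in imputed_vars:
                    continue
                dom = domain_mask(var, df)
                out_of_domain = orig_missing[var] & ~dom
                if out_of_domain.any():
                    df.loc[out_of_domain, var] = np.nan
                to_imp = orig_missing[var] & dom
                if not to_imp.any():
                    continue
                newly = to_imp & df[var].isna()  # entered the domain this sweep
                if newly.any():
                    obs_vals = df.loc[~orig_missing[var] & dom, var].dropna().to_numpy()
                    if obs_vals.size:
                        df.loc[newly, var] = rng.choice(obs_vals, size=int(newly.sum()))
                preds = [p for p in matrix.columns if matrix.loc[var, p] == 1 and p in df.columns]
                fit_rows = dom & ~orig_missing[var] & df[var].notna()
                X_all = build_design(df, preds)
                X_obs = X_all[fit_rows.to_numpy()]
                X_mis = X_all[to_imp.to_numpy()]
                y_obs = df.loc[fit_rows, var]
                method = spec.methods[var]
                if method == "pmm":
                    imputed = impute_pmm(
                        y_obs.to_numpy(dtype=float), X_obs, X_mis, spec.pmm_donors, rng
                    )
                elif method == "logistic":
                    imputed = impute_logistic(y_obs.to_numpy(), X_obs, X_mis, rng)
                elif method == "multinomial":
                    imputed = impute_multinomial(y_obs.to_numpy(object), X_obs, X_mis, rng)
                else:  # pragma: no cover - validated earlier
                    raise AssertionError(method)
                df.loc[to_imp, var] = imputed
            _update_passive(df)
            for var in imputed_vars:
                dom = domain_mask(var, df)
                cells = numeric_code(var, df.loc[orig_missing[var] & dom, var])
                if len(cells):
                    chain_means[var][chain, it] = float(cells.mean())
                    chain_vars[var][chain, it] = float(cells.var(ddof=0))
        completed.append(df)

    # observed values must be untouched
    for var in spec.visit_sequence:
        obs = ~orig_missing[var]
        for df in completed:
            if not df.loc[obs, var].equals(base.loc[obs, var]):
                raise AssertionError(f"observed values of {var!r} were altered")
    return ImputationResult(
        completed=completed, chain_means=chain_means, chain_vars=chain_vars,
        spec=spec, matrix=matrix, originally_missing=orig_missing,
    )


def _update_passive(df: pd.DataFrame) -> None:
    derived = derive_covariates(df)
    for col in derived.columns:
        df[col] = derived[col]


def _nelson_aalen_cumhaz(df: pd.DataFrame) -> np.ndarray:
    """Nelson-Aalen cumulative hazard of overall mortality evaluated at each
    subject's exit time (the optional H(T) predictor)."""
    t = df["followup_days"].to_numpy(dtype=float)
    e = df["dead"].to_numpy(dtype=int)
    grid = np.unique(t[e == 1])
    n_risk = (t[None, :] >= grid[:, None]).sum(axis=1)
    d = np.array([(e[t == g] == 1).sum() for g in grid])
    ch = np.cumsum(d / n_risk)
    idx = np.searchsorted(grid, t, side="right") - 1
    return np.where(idx >= 0, ch[np.clip(idx, 0, None)], 0.0)


# ---------------------------------------------------------------------------
# Observed-vs-imputed diagnostics


def compare_observed_imputed(result: ImputationResult, variable: str):
    """Diagnostic comparison of observed and imputed distributions.

    Categorical variables: per-category observed counts/percentages and
    the min/mean/median/max of the imputed counts across the m datasets,
    plus a chi-square test of observed vs mean-imputed counts.
    Continuous variables: a quantile overlay summary.
    """
    base = result.completed[0]
    var = variable
    if var not in result.chain_means:
        raise ValueError(f"{var!r} was not imputed")
    dom0 = domain_mask(var, base)
    obs_mask = ~result.originally_missing[var]
    imp_mask = dom0 & ~obs_mask

    if var in _CAT_LEVELS or var in ("cN", "cM", "pN"):
        levels = _CAT_LEVELS.get(var, [0, 1])
        obs_counts = base.loc[obs_mask & dom0, var].value_counts().reindex(levels).fillna(0)
        imp_counts = np.stack([
            df.loc[imp_mask, var].value_counts().reindex(levels).fillna(0).to_numpy()
            for df in result.completed
        ])
        table = pd.DataFrame({
            "level": levels,
            "observed_n": obs_counts.to_numpy(int),
            "observed_pct": np.round(100 * obs_counts / max(obs_counts.sum(), 1), 1).to_numpy(),
            "imputed_min": imp_counts.min(axis=0).astype(int),
            "imputed_mean": imp_counts.mean(axis=0),
            "imputed_median": np.median(imp_counts, axis=0),
            "imputed_max": imp_counts.max(axis=0).astype(int),
        })
        mean_imp = imp_counts.mean(axis=0)
        keep = (obs_counts.to_numpy() + mean_imp) > 0
        if keep.sum() >= 2 and obs_counts.to_numpy()[keep].sum() > 0 and mean_imp[keep].sum() > 0:
            chi2, p, _, _ = stats.chi2_contingency(
                np.stack([obs_counts.to_numpy()[keep], mean_imp[keep]])
            )
        else:
            chi2, p = np.nan, np.nan
        table.attrs["chi2"] = float(chi2)
        table.attrs["p_value"] = float(p)
        return table
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    obs_vals = pd.to_numeric(base.loc[obs_mask & dom0, var], errors="coerce").dropna()
    imp_vals = pd.concat(
        [pd.to_numeric(df.loc[imp_mask, var], errors="coerce") for df in result.completed]
    ).dropna()
    table = pd.DataFrame({
        "quantile": qs,
        "observed": obs_vals.quantile(qs).to_numpy(),
        "imputed": imp_vals.quantile(qs).to_numpy(),
    })
    table.attrs["observed_mean"] = float(obs_vals.mean())
    table.attrs["imputed_mean"] = float(imp_vals.mean())
    return table
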