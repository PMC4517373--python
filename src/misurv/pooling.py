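"""Pooling of survival curves across imputations: Rubin's rules on the
complementary log-log scale.

For each imputed dataset i and grid time t the survival estimate S_i(t)
and its variance V_i(t) are mapped to

    Q_i(t) = log(-log(1 - S_i(t)))
    U_i(t) = V_i(t) / [log(1 - S_i(t)) * (1 - S_i(t))]^2   (delta method)

then combined by Rubin's rules,

    Qbar = mean_i Q_i,   Ubar = mean_i U_i,
    B    = (1/(m-1)) sum_i (Q_i - Qbar)^2,
    T    = Ubar + (1 + 1/m) B,

and back-transformed: Sbar = 1 - exp(-exp(Qbar)), with the 95% interval
1 - exp(-exp(Qbar +/- z sqrt(T))).  The cll scale maps probabilities to
the whole real line, so normal-theory pooling behaves well and the
back-transformed interval respects [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import DAYS_PER_YEAR, SurvivalCurve

#: clamp for survival probabilities before transforming (the transform is
#: undefined at S in {0, 1})
CLL_EPS = 1e-10
#: floor for the transformed-scale within-imputation variance
U_FLOOR = 1e-12


def cll_transform(s):
    """Complementary log-log of the failure probability: log(-log(1 - S))."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("survival probabilities must lie in [0, 1]")
    s = np.clip(s, CLL_EPS, 1.0 - CLL_EPS)
    return np.log(-np.log1p(-s))


def cll_back_transform(q):
    """Inverse of :func:`cll_transform`: S = 1 - exp(-exp(Q))."""
    q = np.asarray(q, dtype=float)
    return -np.expm1(-np.exp(q))


def delta_variance(s, var_s):
    """Variance of log(-log(1-S)) by the delta method: Var(S)/[log(1-S)(1-S)]^2."""
    s = np.asarray(s, dtype=float)
    var_s = np.asarray(var_s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("survival probabilities must lie in [0, 1]")
    if np.any(var_s < 0):
        raise ValueError("variances must be nonnegative")
    sc = np.clip(s, CLL_EPS, 1.0 - CLL_EPS)
    denom = (np.log1p(-sc) * (1.0 - sc)) ** 2
    return var_s / denom


def rubin_pool(q_hats, us):
    """Rubin's rules: returns (Q_bar, U_bar, B, T_total).

    ``q_hats``/``us`` have the m per-imputation values along axis 0.
    """
    q = np.asarray(q_hats, dtype=float)
    u = np.asarray(us, dtype=float)
    if q.shape != u.shape:
        raise ValueError("q_hats and us must align")
    m = q.shape[0]
    if m < 2:
        raise ValueError("pooling requires m >= 2 imputations")
    if not (np.isfinite(q).all() and np.isfinite(u).all()):
        raise ValueError("pooling inputs must be finite")
    q_bar = q.mean(axis=0)
    u_bar = u.mean(axis=0)
    b = ((q - q_bar) ** 2).sum(axis=0) / (m - 1)
    t_total = u_bar + (1.0 + 1.0 / m) * b
    return q_bar, u_bar, b, t_total


def relative_efficiency(b, u_bar, m: int):
    """Relative efficiency of m imputations: RE = 1/(1 + gamma/m).

    ``gamma = (B + B/m)/T`` is the fraction of missing information.
    Scalar inputs give a scalar; array inputs are averaged over the grid
    (the conventional "mean relative efficiency").
    """
    b = np.asarray(b, dtype=float)
    u_bar = np.asarray(u_bar, dtype=float)
    t = u_bar + (1.0 + 1.0 / m) * b
    gamma = np.where(t > 0, (b + b / m) / np.where(t > 0, t, 1.0), 0.0)
    re = 1.0 / (1.0 + gamma / m)
    return float(re.mean())


@dataclass
class PooledCurve:
    """Pooled survival curve on the union grid of the m input curves."""

    times: np.ndarray
    s_bar: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    q_bar: np.ndarray
    u_bar: np.ndarray
    b: np.ndarray
    t_total: np.ndarray
    m: int

    def evaluate(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.s_bar[np.clip(idx, 0, None)], 1.0)

    def ci_at(self, t) -> tuple[np.ndarray, np.ndarray]:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        lo = np.where(idx >= 0, self.ci_low[np.clip(idx, 0, None)], 1.0)
        hi = np.where(idx >= 0, self.ci_high[np.clip(idx, 0, None)], 1.0)
        return lo, hi

    def mean_relative_efficiency(self) -> float:
        return relative_efficiency(self.b, self.u_bar, self.m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "s_bar": self.s_bar,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "u_bar": self.u_bar,
                "b": self.b,
                "t_total": self.t_total,
            }
        )

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    def summary_at_years(self, years=(1, 3, 5, 10)) -> pd.DataFrame:
        """Point estimate and 95% CI at the requested follow-up years."""
        days = np.asarray(years, dtype=float) * DAYS_PER_YEAR
        lo, hi = self.ci_at(days)
        return pd.DataFrame(
            {"years": years, "s_bar": self.evaluate(days), "ci_low": lo, "ci_high": hi}
        )


def pool_survival_curves(
    curves: list[SurvivalCurve],
    z: float | None = 1.96,
    barnard_rubin: bool = False,
    n_complete: int | None = None,
) -> PooledCurve:
    """Pool m survival curves by Rubin's rules after cll transformation.

    The curves are evaluated right-continuously on the union of their
    event-time grids.  Grid points where every curve still equals 1
    (before the first pooled event) are passed through untransformed as
    S=1 with a degenerate [1, 1] interval.

    ``barnard_rubin=True`` replaces the fixed normal quantile with a
    t-quantile on Barnard-Rubin adjusted degrees of freedom
    (``n_complete`` = complete-data degrees of freedom; required then).
    """
    if len(curves) < 2:
        raise ValueError("pooling requires m >= 2 curves")
    kinds = {c.kind for c in curves}
    if len(kinds) > 1:
        raise ValueError(f"cannot pool curves of different kinds: {sorted(kinds)}")
    m = len(curves)
    grid = np.unique(np.concatenate([c.times for c in curves]))
    S = np.stack([c.evaluate(grid) for c in curves])      # (m, J)
    V = np.stack([c.variance_at(grid) for c in curves])

    q = cll_transform(S)
    u = np.maximum(delta_variance(S, V), U_FLOOR)
    q_bar, u_bar, b, t_total = rubin_pool(q, u)

    if barnard_rubin:
        if n_complete is None:
            raise ValueError("barnard_rubin requires n_complete")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (1.0 + 1.0 / m) * b / u_bar
            nu_old = (m - 1) * (1.0 + 1.0 / r) ** 2
            nu_com = float(n_complete - 1)
            lam = (1.0 + 1.0 / m) * b / t_total
            nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
            nu = np.where(
                np.isfinite(nu_old), nu_old * nu_obs / (nu_old + nu_obs), nu_obs
            )
        zq = stats.t.ppf(0.975, np.maximum(nu, 1.0))
    else:
        zq = z if z is not None else 1.96

    half = zq * np.sqrt(t_total)
    s_bar = cll_back_transform(q_bar)
    ci_low = cll_back_transform(q_bar - half)
    ci_high = cll_back_transform(q_bar + half)

    # boundary passthrough: points where every estimate sits exactly on a
    # probability boundary (before the first pooled event, or after every
    # curve has absorbed at 0) are reported untransformed with a
    # degenerate interval — the cll scale cannot represent them
    for bound in (1.0, 0.0):
        on_bound = np.all(S == bound, axis=0)
        s_bar[on_bound] = bound
        ci_low[on_bound] = bound
        ci_high[on_bound] = bound
        u_bar[on_bound] = 0.0
        b[on_bound] = 0.0
        t_total[on_bound] = 0.0

    return PooledCurve(
        times=grid, s_bar=s_bar, ci_low=ci_low, ci_high=ci_high,
        q_bar=q_bar, u_bar=u_bar, b=b, t_total=t_total, m=m,
    )
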