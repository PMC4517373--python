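# Methods

`misurv` estimates cause-specific survival in a cohort where a subset of
the causes of death is missing, by multiply imputing the causes (and
incomplete covariates), estimating survival on each completed dataset,
and pooling the curves on the complementary log-log (cll) scale. This
note documents the models, the defaults and their rationale, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the known limitations.

## The estimation problem

For men diagnosed with prostate cancer — typically elderly, with strong
competing mortality — two families of estimators target "survival from
the cancer":

* **Net survival** (Pohar-Perme) needs no causes of death: each
  subject's at-risk and event contributions at follow-up time *t* are
  weighted by the inverse of their expected survival `1/S_pop(t)` from a
  population life table, and net survival is `exp(−Λ_excess)`. Its
  weakness is the life table: a screening cohort is typically healthier
  than the general male population, so the excess hazard can be
  negative and net survival can exceed 100%.
* **Cause-specific survival** needs a cause for every death: either
  Kaplan-Meier censoring other-cause deaths, or the Aalen-Johansen
  competing-risks complement `1 − CIF_cancer`. When causes are partly
  missing, we impute them m times and pool.

## Multiple imputation (fully conditional specification)

Incomplete variables are imputed one at a time in a clinical
chronological visit order (PSA at diagnosis, cT, cN, cM, Gleason group,
first treatment, pT, pN, PSA after treatment, cause of death), sweeping
`n_iter` times per chain, with m independent chains. Defaults `m = 20`,
`n_iter = 20`: the overall missing-cell fraction is around 20%, and the
conventional guidance is m near the percentage of missing information;
20 sweeps is far beyond the handful FCS usually needs, cheap at this
scale.

Per-variable models:

| variable | model |
|---|---|
| PSA (diagnosis, post-treatment) | predictive mean matching, 5 donors |
| cN, cM, pN, cause of death | Bayesian logistic regression |
| cT, Gleason group, first treatment, pT | multinomial logit |
| T_new, N_new, d'Amico group | passive (recomputed, never modelled) |

**Conditional domains.** The cause of death exists only for the
deceased; pathological stage only when the first treatment is surgery.
These variables are imputed only on their domain and are structurally
undefined elsewhere. Because the first treatment can itself be imputed,
the pT/pN domain is re-evaluated every sweep: records drifting out of
the surgery domain have their pathological stage unset; records
drifting in get a fresh draw from the observed marginal before the
model-based imputation next visits them.

**Passive variables.** `T_new`/`N_new` equal the pathological stage
after surgery and the clinical stage otherwise; the d'Amico group is a
deterministic function of PSA, Gleason and stage. They are recomputed
after every sweep so that later targets (notably the cause of death)
see up-to-date values.

**Posterior draws.** PMM draws σ² from SSE/χ²(df) and β from
N(β̂, σ²(XᵀX+κI)⁻¹), predicts observed cases with β̂ and missing cases
with the drawn β (type-1 matching), and donates a uniformly chosen
value among the 5 nearest predicted means. Logistic imputation fits by
Newton/IRLS and perturbs the coefficients by a draw from the inverse
penalised information. The penalty is a weakly-informative Gaussian
prior on the standardised design — sd 2.5 per coefficient, sd 10 for
the intercept — rather than a bare numerical ridge: on small domains
(tens of observed causes against ~20 design columns) the unpenalised
information is near-singular and an "asymptotic" draw would saturate
the predicted probabilities at 0/1, dragging imputed causes toward
50/50. At ordinary sample sizes the prior is numerically irrelevant
(the fit matches an unpenalised statsmodels Logit to 4 decimals).
Multinomial targets are imputed from the fitted class probabilities
*without* a coefficient perturbation: the multinomial information
degenerates under quasi-separation much more readily, and drawing from
a degenerate covariance assigns classes arbitrarily; this mirrors how
the standard chained-equations engines treat unordered categorical
targets.

**Predictor selection.** The default predictor matrix is the bundled
clinically validated one. A quickpred-style constructor is provided:
a predictor is retained when the larger of |corr(values)| and
|corr(missingness indicator, values)| (Pearson, pairwise-complete,
integer-coded categories) is ≥ 0.1 and the proportion of usable cases
is ≥ 0.4; a manual override hook mimics the clinician-edit step.
Follow-up time, the event indicator and a Nelson-Aalen cumulative
hazard transform of time are available as optional predictor columns
but are off by default.

**Convergence.** Chain statistics record the mean and variance of the
imputed cells per variable, chain and sweep. R̂ is the Gelman-Rubin
potential scale reduction computed on the chains of per-sweep means
(all sweeps retained; zero within-chain variance returns 1 by
convention). R̂ < 1.1 is read as convergent. Observed-vs-imputed
diagnostics report per-category observed counts against the
min/mean/median/max of imputed counts across the m datasets with a
chi-square comparison, and a quantile overlay for continuous variables.

## Survival estimation and pooling

Per completed dataset: Kaplan-Meier with Greenwood variance (ties:
deaths before censorings; the curve steps only at event times) and the
Aalen-Johansen CIF with the Aalen/Dinse-Larson variance (numerically
identical to R `survival`'s multistate estimator; R `cmprsk` uses a
different asymptotically equivalent form — the point estimates agree
exactly). Time is in days internally; years (365.25 d/y) only at
reporting.

Pooling evaluates the m step functions right-continuously on the union
of their event grids, maps S to `Q = log(−log(1−S))` with the
delta-method variance `U = Var(S)/[log(1−S)(1−S)]²`, applies Rubin's
rules (`Q̄`, `Ū`, between-variance B, total `T = Ū + (1+1/m)B`), and
back-transforms `S̄ = 1−exp(−exp(Q̄))` with the 95% interval from
`Q̄ ± 1.96√T`. Numerical guards: S is clamped to `[1e−10, 1−1e−10]`
before transforming and U floored at `1e−12`; grid points where every
imputation sits exactly on a probability boundary (all 1 before the
first pooled event, or all 0 after absorption) pass through
untransformed with a degenerate interval, since the cll scale
represents neither boundary. The normal quantile 1.96 is the default;
a Barnard-Rubin t-based correction is available but off. Relative
efficiency is `1/(1+γ/m)` with `γ = (B+B/m)/T`, averaged over the grid.

## Pohar-Perme net survival

The life table stores rates per person-year on a 1-year age × 1-year
period grid; subjects age along the diagonal, and lookups outside the
grid clamp to the nearest cell with a warning. The estimator is
integrated over the partition given by all exit times, on which the
risk set is constant; the subject-level population-hazard integral uses
the exact identity `∫ₐᵇ w dΛ_pop = w(b) − w(a)` with `w = 1/S_pop`, so
under a zero-hazard table the estimator reduces *exactly* to
exp(−Nelson-Aalen). The variance is the Poisson-type form
`Σ w² dN / (Σ w Y)²` on the hazard scale, delta-transformed to the
survival scale. Net survival may exceed 1 and no correction is applied
— that behavior is diagnostic, not an error.

## Sensitivity protocols

1. **Random removal**: from a cohort whose causes are all known — all
   the dead plus a seeded random half of the living — mask
   10/30/50/70/90% of causes uniformly (MCAR by construction),
   re-impute with the same model, pool, compare against the sub-cohort's
   true cause-specific curve.
2. **Re-impute the originally observed**: within each first-level
   completed dataset, delete exactly the causes that were genuinely
   observed, keep the first-level imputations as pseudo-truth, and
   re-impute.
3. **Cross-validation**: as (2) but masking a uniform random draw of
   the same size among all deaths of the completed dataset.

**Coverage metric.** The protocols are summarised by the fraction of
pooled-grid points at which the reference curve lies inside the pooled
95% interval, *restricted to points where the reference curve has
started (truth < 1)*: before its first event the reference sits exactly
on the boundary, which the cll interval excludes by construction
whenever any imputation carries an earlier event, so pre-onset points
would record a boundary artifact as a miss. The source comparisons in
this literature are visual; the scalar is this package's own metric.

## Synthetic-data generator

The generator emulates a prostate-cancer screening cohort: n = 2844,
ages truncated-normal on [56, 78] (mean 67, sd 5.5), diagnosis years
2003–2011 with administrative censoring mid-2013 and 1%/year loss to
follow-up; a latent severity factor links PSA, Gleason group, stage,
nodal/metastatic status and treatment choice, so the covariates carry
genuine information about the cause of death. Event times follow
cause-specific proportional hazards with closed-form cumulative
hazards: Weibull (shape 1.6) for prostate-cancer death and Gompertz in
attained age for other causes, calibrated once so that ~10–11% die
within follow-up with roughly a 1:2 prostate:other split. The
other-cause level is set *below* the bundled Gompertz life-table preset
(the healthy-screenee effect), which is what makes net survival exceed
100% in the first years. Covariate missingness is MCAR per variable at
registry-like rates; the cause of death is masked at a 50% target by a
configurable mechanism — MCAR, MAR with log-odds increasing in
diagnosis year (emulating a cause-of-death request that lags the
calendar), or MNAR depending on the true cause (a deliberate negative
control).

The truth object returns the exact generating cause-specific (net)
survival, `mean_i exp(−Λ_prostate,i(t))` over the realized covariates.

What the generator does **not** emulate: the joint covariate
distribution of any real registry beyond configured marginals and the
single latent factor; non-proportional hazards; cause
misclassification; informative censoring. Passing tests therefore show
that the pipeline is correct and well calibrated under a plausible MAR
data-generating process — not that any particular registry's
missingness is MAR.

## Problem sizes used by the test suite

The acceptance-style tests run the full pipeline at the study scale
(n = 2844 cohorts, m = 20) for the masking protocols, with 5 sweeps per
chain there (chains mix within a few sweeps; R̂ is checked separately
with 20 × 20 chains at n = 1000), 2–4 replicate seeds per masking
fraction, and reduced m for the estimator-agreement check. These sizes
are the package's chosen trade-off between Monte-Carlo resolution and a
test suite that runs in minutes.

## Known limitations

* At extreme masking (90% of causes missing, ~16 observed causes) the
  imputation model is fit on a sliver of data. When that sliver is
  unrepresentative — the binomial sd of the observed prostate fraction
  alone is ~0.11 there — all m imputations inherit the same bias and
  the between-imputation variance cannot reflect it, so the pooled 95%
  band under-covers in a nontrivial fraction of replicates (mean
  pointwise coverage ≈ 0.8 across seeds at study scale; ≥ 0.95 per
  replicate at ≤ 70% masking). This anti-conservatism of MI intervals
  under a weak imputation model is inherent, not a defect of the
  pooling arithmetic.
* MNAR missingness is not identifiable from observed data; the MNAR
  generator exists purely as a negative control, and no delta-adjusted
  sensitivity imputation is provided.
* The multinomial imputer omits parameter-uncertainty draws (see
  above); for variables with few missing values the effect is
  negligible, but it slightly understates between-imputation variance
  for heavily missing unordered targets.
* The clinically validated predictor matrix contains a deliberate
  circularity: the d'Amico group helps predict cN while being passively
  derived from it. Imputed cN = 1 states can self-reinforce through
  that near-separated passive predictor, so cN mixes slowest of all the
  variables and its R̂ can exceed 1.1 on some seeds at full scale —
  exactly the variable the convergence diagnostic exists to flag.
  Dropping the composite from its components' predictor rows removes
  the effect if desired (the matrix is editable via the override hook).
* The Pohar-Perme variance ignores the uncertainty of the life table
  itself, as is conventional.
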