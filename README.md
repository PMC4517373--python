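# misurv

Cause-specific survival for cancer-registry cohorts in which a subset of
the causes of death is missing.

Cancer registries often know *that* a patient died long before they know
*why*: cause-of-death linkage lags the calendar, certificates go
missing, patients move abroad. For an elderly-onset cancer such as
prostate cancer this matters, because most deaths are from other causes
and naive analyses either treat every death as a cancer death or lean on
population life tables (net survival) that do not represent the cohort.
`misurv` implements the third route: **multiply impute the missing
causes of death, estimate cause-specific survival on each completed
dataset, and pool the curves with Rubin's rules on the complementary
log-log scale** — alongside the net-survival estimator it is meant to be
compared with, MCAR/MAR screening diagnostics, and masking-based
validation protocols.

## The core method

For each of m imputed datasets *i* and each event time *t*, take the
survival estimate Ŝᵢ(t) and its variance V[Ŝᵢ(t)] (Kaplan-Meier with
Greenwood variance censoring other-cause deaths, or the competing-risks
complement 1 − CIF with the Aalen variance), map them to the real line,

    Q̂ᵢ(t) = log(−log[1 − Ŝᵢ(t)]),
    Uᵢ(t) = V[Ŝᵢ(t)] / ( log(1 − Ŝᵢ(t)) · (1 − Ŝᵢ(t)) )²   (delta method),

pool by Rubin's rules,

    Q̄ = (1/m) Σ Q̂ᵢ,   Ū = (1/m) Σ Uᵢ,
    B = 1/(m−1) Σ (Q̂ᵢ − Q̄)²,   T = Ū + (1 + 1/m) B,

and back-transform the estimate and its 95% interval:

    S̄(t) = 1 − exp(−exp(Q̄(t))),
    CI(t) = 1 − exp(−exp(Q̄(t) ± 1.96 √T(t))).

The imputation engine is a fully conditional specification with
predictive mean matching for continuous variables, Bayesian logistic /
multinomial-logit models for categorical ones, *conditional domains*
(cause of death only among the deceased, pathological stage only after
surgery), *passive* derived variables (T_new, N_new, d'Amico risk
group), quickpred-style predictor selection, and Gelman-Rubin R̂
convergence diagnostics. The Pohar-Perme net-survival estimator (which
can exceed 100% in a cohort healthier than its life table) is provided
for comparison, and three sensitivity protocols mask known causes and
check that the truth stays inside the pooled band.

## Worked example

```python
from misurv import (GeneratorConfig, ImputationSpec, generate_cohort,
                    generate_life_table, run_chained_equations,
                    survival_comparison)

cohort, truth = generate_cohort(GeneratorConfig(n=1500, seed=3))
result = run_chained_equations(cohort, ImputationSpec(m=10, n_iter=8, seed=4))
print(survival_comparison(cohort, result, generate_life_table())
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

prints (run as `python examples/03_pooled_survival_comparison.py`):

```
stratum  years    n  overall   net  pooled_km  pooled_cr
    all      1 1500    0.985 1.001      0.997      0.997
    all      3 1500    0.949 1.000      0.989      0.989
    all      5 1500    0.906 0.997      0.976      0.977
    all     10 1500    0.761 0.971      0.929      0.935

true (generating) cause-specific survival at the same times:
[0.998 0.989 0.976 0.932]
```

Overall survival falls to 0.76 by 10 years, but most of those deaths
are from other causes: the pooled cause-specific estimates (KM and
competing-risks, nearly identical — evidence the two readings agree
under independent hazards) put survival from the cancer itself at ~0.93,
tracking the generating truth. Net survival exceeds 1 in the first
years (the screened cohort dies less than the life table predicts) and
drifts above the cause-specific estimates later — it needs no causes of
death but inherits the life table's biases.

The other examples cover the generator (`01`), imputation and
convergence diagnostics (`02`), MCAR/MAR screening (`04`) and the
masking/re-imputation sensitivity protocols (`05`). A thin CLI wraps the
same pipeline for shell use:

```
misurv simulate --n 2844 --seed 1 --out runs/sim
misurv survival --cohort runs/sim/cohort.csv --life-table runs/sim/life_table.tsv \
                --m 20 --iterations 20 --seed 2 --out runs/surv
misurv sensitivity --cohort runs/sim/cohort.csv --protocol 1 --seed 3 --out runs/sens
```

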