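"""Chained-equations imputation with convergence diagnostics.

Imputes all incomplete variables (cause of death only among the
deceased, pathological stage only after surgery), then prints the
Gelman-Rubin R-hat per variable — values below 1.1 indicate the chains
mixed — and the observed-vs-imputed comparison for the cause of death.
"""

from misurv import (
    GeneratorConfig, ImputationSpec, compare_observed_imputed, generate_cohort,
    run_chained_equations,
)

cohort, _ = generate_cohort(GeneratorConfig(n=1200, seed=1))
spec = ImputationSpec(m=10, n_iter=10, seed=2)  # m=20/iter=20 for production runs
result = run_chained_equations(cohort, spec)

print("R-hat per imputed variable (convergent if < 1.1):")
print(result.rhat().round(3).to_string())
print("(cN mixes slowest: the d'Amico group predicts cN while being derived")
print(" from it, a circularity in the clinical predictor matrix that this")
print(" diagnostic exists to flag; see docs/methods.md)")

tab = compare_observed_imputed(result, "cause")
print("\nobserved vs imputed causes of death (counts across the m datasets):")
print(tab.to_string(index=False))
print(f"chi-square p (observed vs mean imputed) = {tab.attrs['p_value']:.2f}")
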