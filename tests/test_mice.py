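import numpy as np
import pandas as pd
import pytest

from misurv import (
    Cohort, ImputationSpec, clinical_predictor_matrix, compare_observed_imputed,
    derive_covariates, impute_logistic, impute_multinomial, impute_pmm, quickpred,
    rhat, run_chained_equations,
)
from misurv.mice import apply_overrides, validate_predictor_matrix

from conftest import make_cohort_df


class TestQuickpred:
    def _table(self, rng, n=400):
        x = rng.normal(size=n)
        df = make_cohort_df(n, followup_days=list(range(1, n + 1)))
        df["psa_diag"] = np.exp(np.log(7) + 0.6 * x + 0.1 * rng.normal(size=n))  # strong corr
        df["age_at_diagnosis"] = 65 + rng.normal(size=n)                 # no corr
        df["psa_post"] = np.exp(0.02 * x + rng.normal(scale=2.0, size=n))  # weak corr
        df.loc[rng.choice(n, 80, replace=False), "psa_diag"] = np.nan
        return Cohort(df), x

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(0)
        cohort, _ = self._table(rng)
        df = cohort.with_derived().data
        mat = quickpred(cohort, 0.1, 0.4)
        from misurv.mice import MATRIX_VARIABLES, numeric_code

        target = "psa_diag"
        for pred in MATRIX_VARIABLES:
            if pred == target or pred not in df.columns:
                continue
            tv, pv = numeric_code(target, df[target]), numeric_code(pred, df[pred])
            if pv.dropna().nunique() <= 1:
                continue
            miss = tv.isna()
            usable = pv[miss].notna().mean()
            both = tv.notna() & pv.notna()
            r1 = abs(np.corrcoef(tv[both], pv[both])[0, 1]) if pv[both].nunique() > 1 else 0
            obs = pv.notna()
            r2 = (abs(np.corrcoef(miss[obs].astype(float), pv[obs])[0, 1])
                  if miss[obs].nunique() > 1 else 0)
            expected = int(max(r1, r2) >= 0.1 and usable >= 0.4)
            assert mat.loc[target, pred] == expected, pred

    def test_low_correlation_gate(self):
        # correlation far below threshold, perfect usable fraction -> excluded
        rng = np.random.default_rng(1)
        cohort, _ = self._table(rng)
        mat = quickpred(cohort, min_correlation=0.1, min_usable_fraction=0.4)
        assert mat.loc["psa_diag", "age_at_diagnosis"] == 0

    def test_usable_cases_gate(self):
        n = 300
        rng = np.random.default_rng(2)
        df = make_cohort_df(n, followup_days=list(range(1, n + 1)))
        x = rng.normal(size=n)
        df["psa_diag"] = np.exp(np.log(7) + 0.5 * x)
        df["psa_post"] = np.exp(0.5 * x + rng.normal(scale=0.1, size=n))
        miss_rows = rng.choice(n, 100, replace=False)
        df.loc[miss_rows, "psa_diag"] = np.nan
        # predictor unobserved on most target-missing rows -> usable < 0.4
        df.loc[miss_rows[:80], "psa_post"] = np.nan
        mat = quickpred(Cohort(df), 0.1, 0.4)
        assert mat.loc["psa_diag", "psa_post"] == 0

    def test_passive_and_complete_rows_are_zero(self):
        rng = np.random.default_rng(3)
        cohort, _ = self._table(rng)
        mat = quickpred(cohort)
        for var in ("age_at_diagnosis", "T_new", "N_new", "damico_group"):
            assert mat.loc[var].sum() == 0

    def test_override_hook_and_validation(self):
        mat = clinical_predictor_matrix()
        out = apply_overrides(mat, unset_pairs=[("cause", "psa_post")])
        assert out.loc["cause", "psa_post"] == 0
        with pytest.raises(ValueError, match="diagonal"):
            apply_overrides(mat, set_pairs=[("cause", "cause")])


class TestImputePMM:
    def test_constant_donor_pool(self):
        rng = np.random.default_rng(0)
        out = impute_pmm(np.full(30, 7.0), np.random.randn(30, 2), np.random.randn(5, 2), rng=rng)
        assert (out == 7.0).all()

    def test_outputs_are_observed_values(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        out = impute_pmm(y, rng.normal(size=(50, 3)), rng.normal(size=(20, 3)), rng=rng)
        assert np.isin(out, y).all()

    def test_tracks_linear_generator(self):
        rng = np.random.default_rng(2)
        x_obs = rng.uniform(-2, 2, size=500)
        y_obs = 2 * x_obs + rng.normal(scale=0.1, size=500)
        x_mis = np.array([-1.0, 0.0, 1.5])
        draws = np.stack([
            impute_pmm(y_obs, x_obs[:, None], x_mis[:, None], rng=np.random.default_rng(k))
            for k in range(500)
        ])
        np.testing.assert_allclose(draws.mean(axis=0), 2 * x_mis, atol=0.1)


class TestImputeLogistic:
    def test_degenerate_single_class(self):
        with pytest.warns(UserWarning, match="single observed class"):
            out = impute_logistic(np.ones(20), np.random.randn(20, 2), np.random.randn(4, 2))
        assert (out == 1).all()

    def test_null_signal_preserves_prevalence(self):
        rng = np.random.default_rng(3)
        y = (rng.random(400) < 0.3).astype(int)
        x = rng.normal(size=(400, 2))
        draws = np.concatenate([
            impute_logistic(y, x, rng.normal(size=(10, 2)), rng=np.random.default_rng(k))
            for k in range(100)
        ])
        assert draws.mean() == pytest.approx(0.3, abs=0.05)

    def test_strong_signal_matches_bayes_rule(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(600, 1))
        p = 1 / (1 + np.exp(-3 * x[:, 0]))
        y = (rng.random(600) < p).astype(int)
        x_mis = np.array([[-2.0]] * 50 + [[2.0]] * 50)
        out = impute_logistic(y, x, x_mis, rng=rng)
        bayes = np.array([0] * 50 + [1] * 50)
        assert (out == bayes).mean() >= 0.8


class TestImputeMultinomial:
    def test_degenerate_single_category(self):
        with pytest.warns(UserWarning, match="single observed category"):
            out = impute_multinomial(np.array(["A"] * 15, dtype=object),
                                     np.random.randn(15, 2), np.random.randn(6, 2))
        assert (out == "A").all()

    def test_null_signal_preserves_frequencies(self):
        rng = np.random.default_rng(5)
        y = rng.choice(["A", "B", "C"], p=[0.5, 0.3, 0.2], size=500).astype(object)
        x = rng.normal(size=(500, 2))
        draws = np.concatenate([
            impute_multinomial(y, x, rng.normal(size=(20, 2)), rng=np.random.default_rng(k))
            for k in range(60)
        ])
        freq = pd.Series(draws).value_counts(normalize=True)
        assert freq["A"] == pytest.approx(0.5, abs=0.06)
        assert freq["B"] == pytest.approx(0.3, abs=0.06)
        assert freq["C"] == pytest.approx(0.2, abs=0.06)

    def test_separable_classes_recovered(self):
        rng = np.random.default_rng(6)
        centers = {"A": -3.0, "B": 0.0, "C": 3.0}
        y = rng.choice(["A", "B", "C"], size=300).astype(object)
        x = np.array([centers[v] for v in y])[:, None] + rng.normal(scale=0.5, size=(300, 1))
        x_mis = np.array([[-3.0]] * 30 + [[0.0]] * 30 + [[3.0]] * 30)
        out = impute_multinomial(y, x, x_mis, rng=rng)
        want = np.array(["A"] * 30 + ["B"] * 30 + ["C"] * 30, dtype=object)
        assert (out == want).mean() >= 0.8


class TestChainedEquations:
    def test_no_missing_values_yields_identical_copies(self):
        df = make_cohort_df(8)
        spec = ImputationSpec(m=3, n_iter=2, seed=0)
        res = run_chained_equations(Cohort(df), spec)
        assert res.m == 3
        for d in res.completed[1:]:
            pd.testing.assert_frame_equal(res.completed[0], d)

    def test_seed_determinism(self, masked_cohort_and_truth):
        cohort, _ = masked_cohort_and_truth
        spec = ImputationSpec(m=2, n_iter=2, seed=13)
        r1 = run_chained_equations(cohort, spec)
        r2 = run_chained_equations(cohort, spec)
        for a, b in zip(r1.completed, r2.completed):
            pd.testing.assert_frame_equal(a, b)
        for var in r1.chain_means:
            np.testing.assert_array_equal(r1.chain_means[var], r2.chain_means[var])

    def test_observed_values_never_altered(self, masked_cohort_and_truth, mice_result):
        cohort, _ = masked_cohort_and_truth
        base = cohort.with_derived().data
        for var, miss in mice_result.originally_missing.items():
            for d in mice_result.completed:
                obs = ~miss
                assert d.loc[obs, var].equals(base.loc[obs, var])

    def test_domain_restrictions_hold_in_every_completed_cohort(self, mice_result):
        for d in mice_result.completed:
            dead = d["dead"] == 1
            assert d.loc[dead, "cause"].notna().all()
            assert d.loc[~dead, "cause"].isna().all()
            surgery = d["first_treatment"] == "surgery"
            assert d.loc[surgery, "pT"].notna().all()
            assert d.loc[~surgery, "pT"].isna().all()
            assert d.loc[surgery, "pN"].notna().all()
            assert d.loc[~surgery, "pN"].isna().all()

    def test_passive_consistency(self, mice_result):
        for d in mice_result.completed:
            rec = derive_covariates(d)
            for col in ("T_new", "N_new", "damico_group"):
                got, want = d[col], rec[col]
                assert ((got == want) | (got.isna() & want.isna())).all()

    def test_no_missing_left_in_imputed_variables(self, mice_result):
        from misurv.mice import domain_mask

        for d in mice_result.completed:
            for var in mice_result.spec.visit_sequence:
                assert d.loc[domain_mask(var, d), var].notna().all(), var


class TestRhat:
    def test_constant_equal_chains_return_one(self):
        with pytest.warns(UserWarning, match="convention"):
            assert rhat(np.full((4, 10), 2.5)) == 1.0

    def test_iid_chains_below_threshold(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            if rhat(rng.normal(size=(20, 20))) < 1.1:
                hits += 1
        assert hits >= 38  # >= 95% of seeds

    def test_disjoint_chains_blow_up(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 20)) * 0.1
        chains[1] += 10.0
        assert rhat(chains) > 5.0

    def test_requires_two_chains_and_iterations(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 10)))


class TestObservedVsImputed:
    def test_observed_percentages_reported(self):
        # 161 observed causes split 106 other / 55 prostate
        n = 400
        df = make_cohort_df(n, followup_days=list(range(1, n + 1)))
        df.loc[: 321, "dead"] = 1
        df.loc[: 105, "cause"] = "other"
        df.loc[106:160, "cause"] = "prostate"
        spec = ImputationSpec(m=3, n_iter=2, seed=1)
        res = run_chained_equations(Cohort(df), spec)
        tab = compare_observed_imputed(res, "cause").set_index("level")
        assert tab.loc["other", "observed_n"] == 106
        assert tab.loc["other", "observed_pct"] == 65.8
        assert tab.loc["prostate", "observed_pct"] == 34.2

    def test_matching_marginals_give_large_p(self, mice_result):
        tab = compare_observed_imputed(mice_result, "cause")
        assert tab.attrs["p_value"] > 0.05

    def test_shifted_distribution_detected(self):
        from scipy import stats

        obs = np.array([100, 50])
        shifted = np.array([30, 120])
        _, p, _, _ = stats.chi2_contingency(np.stack([obs, shifted]))
        assert p < 0.05

    def test_continuous_variable_quantile_overlay(self, mice_result):
        tab = compare_observed_imputed(mice_result, "psa_diag")
        assert list(tab.columns) == ["quantile", "observed", "imputed"]
        assert np.isfinite(tab["imputed"]).all()


class TestCalibration:
    def test_imputed_cause_proportions_recover_truth_under_mar(self):
        """With MAR-masked causes, the completed-data cause proportions
        should track the generating proportions within Monte-Carlo error."""
        from misurv import GeneratorConfig, generate_cohort

        cfg = GeneratorConfig(n=1500, seed=21)
        cohort, truth = generate_cohort(cfg)
        spec = ImputationSpec(m=8, n_iter=6, seed=9)
        res = run_chained_equations(cohort, spec)
        true_p = float((truth.true_cause.dropna() == "prostate").mean())
        imp_p = float(np.mean([
            (d.loc[d["dead"] == 1, "cause"] == "prostate").mean() for d in res.completed
        ]))
        n_dead = int((cohort.data["dead"] == 1).sum())
        mc_se = np.sqrt(true_p * (1 - true_p) / n_dead)
        assert abs(imp_p - true_p) < 3 * mc_se + 0.02


class TestStatsmodelsCrossCheck:
    def test_logistic_fit_matches_statsmodels(self):
        """The in-package IRLS (tiny ridge) agrees with an unpenalised
        statsmodels Logit fit on well-conditioned data."""
        import statsmodels.api as sm

        from misurv._glm import fit_logistic

        rng = np.random.default_rng(0)
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 1] - 0.5 * X[:, 2])))
        y = (rng.random(n) < p).astype(float)
        beta, cov = fit_logistic(X, y)
        fit = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(beta, fit.params, atol=1e-4)
        np.testing.assert_allclose(cov, fit.cov_params(), rtol=5e-3, atol=1e-4)


class TestConfigSerialization:
    def test_spec_yaml_round_trip(self, tmp_path):
        spec = ImputationSpec(m=7, n_iter=3, seed=11, pmm_donors=4)
        p = tmp_path / "spec.yaml"
        spec.to_yaml(p)
        assert ImputationSpec.from_yaml(p) == spec

    def test_predictor_matrix_round_trip(self, tmp_path):
        from misurv.mice import read_predictor_matrix, write_predictor_matrix

        mat = clinical_predictor_matrix()
        p = tmp_path / "matrix.csv"
        write_predictor_matrix(mat, p)
        pd.testing.assert_frame_equal(read_predictor_matrix(p), mat)
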