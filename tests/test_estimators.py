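import numpy as np
import pandas as pd
import pytest

from misurv import (
    GeneratorConfig, LifeTable, cause_specific_km, cumulative_incidence,
    generate_cohort, generate_life_table, kaplan_meier, nelson_aalen_survival,
    pohar_perme,
)

# 6-subject toy set used throughout: exit times and causes
TOY_TIMES = np.array([2.0, 4, 4, 6, 8, 10])
TOY_DEAD = np.array([1, 1, 0, 1, 1, 0])
TOY_CAUSE = np.array(["prostate", "other", None, "prostate", "other", None], dtype=object)


class TestKaplanMeier:
    def test_hand_product_limit_all_events(self):
        km = kaplan_meier([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.estimate, [2 / 3, 1 / 3, 0.0])

    def test_hand_greenwood_variance(self):
        km = kaplan_meier([1, 2, 3], [1, 1, 1])
        assert km.variance[0] == pytest.approx((2 / 3) ** 2 * (1 / 6), abs=1e-12)

    def test_all_censored_flat_at_one(self):
        km = kaplan_meier([5, 9, 12], [0, 0, 0])
        assert (km.evaluate([1, 6, 20]) == 1.0).all()
        assert (km.variance == 0).all()

    def test_right_continuity_and_late_censoring_invariance(self):
        # moving a censoring beyond the last event leaves the curve unchanged,
        # and censorings never add grid points
        km1 = kaplan_meier([1, 2, 3], [1, 1, 0])
        km2 = kaplan_meier([1, 2, 50], [1, 1, 0])
        np.testing.assert_array_equal(km1.times, km2.times)
        np.testing.assert_array_equal(km1.estimate, km2.estimate)
        # right-continuous: value AT an event time is the post-jump value
        assert km1.evaluate(1.0) == pytest.approx(2 / 3)

    def test_tied_censoring_handled_after_event(self):
        # censored subject at t=2 is still at risk for the event at t=2
        km = kaplan_meier([2, 2, 5], [1, 0, 0])
        assert km.estimate[0] == pytest.approx(2 / 3)

    def test_matches_r_survfit_on_toy_set(self):
        # frozen from R survival::survfit on the same data
        km = cause_specific_km(TOY_TIMES, TOY_DEAD, TOY_CAUSE)
        np.testing.assert_allclose(km.estimate, [0.8333333, 0.5555556], rtol=1e-6)
        np.testing.assert_allclose(np.sqrt(km.variance), [0.152, 0.248], atol=5e-4)


class TestCauseSpecificKM:
    def test_single_cause_equals_overall_km(self):
        t, d = np.array([3.0, 5, 7, 9]), np.array([1, 1, 0, 1])
        cause = np.where(d == 1, "prostate", None).astype(object)
        cs = cause_specific_km(t, d, cause)
        km = kaplan_meier(t, d)
        np.testing.assert_array_equal(cs.times, km.times)
        np.testing.assert_array_equal(cs.estimate, km.estimate)
        np.testing.assert_array_equal(cs.variance, km.variance)

    def test_all_other_cause_deaths_flat(self):
        cause = np.array(["other", "other", None], dtype=object)
        cs = cause_specific_km([4, 6, 8], [1, 1, 0], cause)
        assert (cs.estimate == 1.0).all()

    def test_missing_cause_among_dead_rejected(self):
        cause = np.array([None, "other", None], dtype=object)
        with pytest.raises(ValueError, match="missing cause"):
            cause_specific_km([4, 6, 8], [1, 1, 0], cause)


class TestCumulativeIncidence:
    def test_hand_aalen_johansen_on_toy_set(self):
        # hand product construction (matches R cmprsk::cuminc point estimates)
        cr = cumulative_incidence(TOY_TIMES, TOY_DEAD, TOY_CAUSE)
        np.testing.assert_allclose(cr.cif["prostate"], [1 / 6, 1 / 6, 7 / 18, 7 / 18], atol=1e-12)
        np.testing.assert_allclose(cr.cif["other"], [0, 1 / 6, 1 / 6, 7 / 18], atol=1e-12)

    def test_variance_matches_r_survfit_multistate(self):
        # frozen from R survival::survfit(Surv(time, factor(status)) ~ 1)
        cr = cumulative_incidence(TOY_TIMES, TOY_DEAD, TOY_CAUSE)
        np.testing.assert_allclose(
            cr.cif_variance["prostate"],
            [0.02314815, 0.02314815, 0.04783951, 0.04783951], rtol=1e-6,
        )
        np.testing.assert_allclose(
            cr.cif_variance["other"],
            [0.0, 0.02314815, 0.02314815, 0.04783951], rtol=1e-6, atol=1e-12,
        )

    def test_conservation_identity(self):
        cr = cumulative_incidence(TOY_TIMES, TOY_DEAD, TOY_CAUSE)
        total = cr.overall_survival + sum(cr.cif.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_single_cause_cif_is_one_minus_km(self):
        t, d = np.array([3.0, 5, 7, 9]), np.array([1, 1, 0, 1])
        cause = np.where(d == 1, "prostate", None).astype(object)
        cr = cumulative_incidence(t, d, cause)
        km = kaplan_meier(t, d)
        np.testing.assert_allclose(cr.cif["prostate"], 1.0 - km.estimate, atol=1e-12)

    def test_conservation_on_synthetic_cohort(self, masked_cohort_and_truth):
        cohort, truth = masked_cohort_and_truth
        df = cohort.data.copy()
        df["cause"] = truth.true_cause
        cr = cumulative_incidence(df["followup_days"], df["dead"], df["cause"])
        total = cr.overall_survival + sum(cr.cif.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-12)


class TestLifeTable:
    def test_round_trip(self, tmp_path):
        lt = generate_life_table(ages=range(60, 70), years=range(2004, 2010))
        p = tmp_path / "lt.tsv"
        lt.write(p)
        back = LifeTable.read(p)
        np.testing.assert_allclose(back.rates["male"], lt.rates["male"])

    def test_clamping_warns_outside_coverage(self):
        lt = generate_life_table(ages=range(60, 70), years=range(2004, 2010))
        with pytest.warns(UserWarning, match="clamp"):
            r = lt.annual_rate("male", 120, 2005)
        assert r[0] == lt.rates["male"][-1, np.searchsorted(lt.years, 2005)]

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            LifeTable(ages=[60], years=[2000], rates={"male": np.array([[-0.1]])})

    def test_gompertz_preset_increasing_in_age(self):
        lt = generate_life_table()
        col = lt.rates["male"][:, 0]
        assert (np.diff(col) > 0).all()


class TestPoharPerme:
    def test_zero_population_hazard_equals_exp_nelson_aalen(self):
        rng = np.random.default_rng(3)
        t = rng.integers(10, 3000, size=80).astype(float)
        d = rng.integers(0, 2, size=80)
        lt = generate_life_table(preset="zero")
        pp = pohar_perme(t, d, np.full(80, 65.0), np.full(80, 2005), "male", lt)
        na = nelson_aalen_survival(t, d)
        np.testing.assert_array_equal(pp.times, na.times)
        np.testing.assert_allclose(pp.estimate, na.estimate, atol=1e-12)
        np.testing.assert_allclose(pp.variance, na.variance, atol=1e-12)

    def test_net_survival_near_one_when_dying_at_population_rates(self):
        # simulate all-cause deaths exactly from the life-table hazard
        lt = generate_life_table()
        rng = np.random.default_rng(7)
        n = 2000
        age = rng.uniform(60, 75, n)
        year = rng.integers(2003, 2010, n)
        a, b = 3.2e-5, 0.091
        u = rng.random(n)
        t_death = (np.log(np.exp(b * age) + b * (-np.log(u)) / a) / b - age) * 365.25
        t_cens = rng.uniform(1500, 3600, n)
        dead = (t_death <= t_cens).astype(int)
        t = np.maximum(np.minimum(t_death, t_cens), 1.0)
        pp = pohar_perme(t, dead, age, year, "male", lt)
        checks = pp.evaluate([365.25, 3 * 365.25, 7 * 365.25])
        np.testing.assert_allclose(checks, 1.0, atol=0.05)

    def test_net_survival_exceeds_one_for_healthy_cohort(self):
        # cohort dying at half the population rate: net survival > 1
        lt = generate_life_table()
        rng = np.random.default_rng(11)
        n = 2000
        age = rng.uniform(60, 75, n)
        year = rng.integers(2003, 2010, n)
        a, b = 3.2e-5 / 2.0, 0.091
        u = rng.random(n)
        t_death = (np.log(np.exp(b * age) + b * (-np.log(u)) / a) / b - age) * 365.25
        t_cens = rng.uniform(1500, 3600, n)
        dead = (t_death <= t_cens).astype(int)
        t = np.maximum(np.minimum(t_death, t_cens), 1.0)
        pp = pohar_perme(t, dead, age, year, "male", lt)
        assert pp.evaluate(2 * 365.25)[0] > 1.0

    def test_invariant_to_life_table_cells_outside_coverage(self):
        rng = np.random.default_rng(5)
        t = rng.integers(30, 3000, size=60).astype(float)
        d = rng.integers(0, 2, size=60)
        age = rng.uniform(60, 70, 60)
        year = rng.integers(2004, 2008, 60)
        small = generate_life_table(ages=range(55, 85), years=range(2000, 2015))
        big = generate_life_table(ages=range(40, 105), years=range(1990, 2030))
        pp1 = pohar_perme(t, d, age, year, "male", small)
        pp2 = pohar_perme(t, d, age, year, "male", big)
        np.testing.assert_allclose(pp1.estimate, pp2.estimate, atol=1e-12)


class TestLifelinesCrossCheck:
    """lifelines is the independent implementation used only to corroborate
    the in-package product-limit estimator."""

    def test_km_matches_lifelines(self, masked_cohort_and_truth):
        from lifelines import KaplanMeierFitter

        cohort, _ = masked_cohort_and_truth
        d = cohort.data
        km = kaplan_meier(d["followup_days"], d["dead"])
        fitter = KaplanMeierFitter().fit(d["followup_days"], d["dead"])
        theirs = fitter.survival_function_at_times(km.times).to_numpy()
        np.testing.assert_allclose(km.estimate, theirs, atol=1e-12)

    def test_nelson_aalen_matches_lifelines(self, masked_cohort_and_truth):
        from lifelines import NelsonAalenFitter

        cohort, _ = masked_cohort_and_truth
        d = cohort.data
        na = nelson_aalen_survival(d["followup_days"], d["dead"])
        fitter = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(
            d["followup_days"], d["dead"]
        )
        theirs = np.exp(-fitter.cumulative_hazard_at_times(na.times).to_numpy())
        np.testing.assert_allclose(na.estimate, theirs, atol=1e-12)
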