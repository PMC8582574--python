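"""KM estimator, log-rank test, Cox fits and the median-split screen."""
import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from mirnet import (
    SampleAnnotation,
    SurvivalRecord,
    ValidationError,
    ValueKind,
    cox_score_test,
    cox_univariate,
    km_estimate,
    logrank_test,
    median_split,
    survival_screen,
)
from mirnet.simulate import SimConfig, simulate_cohort

from conftest import make_matrix


def records(times, events, prefix="s"):
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), bool(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


def random_cohort(rng, n=40, round_times=True):
    t = rng.exponential(100.0, n)
    if round_times:
        t = np.round(t) + 1.0  # induce ties
    e = rng.random(n) < 0.75
    x = (rng.random(n) < 0.5).astype(float)
    return t, e, x


class TestMedianSplit:
    def test_even_n_midpoint_median(self):
        assert np.array_equal(median_split([1, 2, 3, 4]), [False, False, True, True])

    def test_ties_at_median_go_low(self):
        assert np.array_equal(median_split([1, 2, 2, 3]), [False, False, False, True])

    def test_odd_n_distinct_high_group_size(self, rng):
        for n in (5, 7, 11, 21):
            v = rng.permutation(n).astype(float)
            assert median_split(v).sum() == (n - 1) // 2

    def test_constant_values_rejected(self):
        with pytest.raises(ValidationError, match="identical"):
            median_split([2.0, 2.0, 2.0, 2.0])

    def test_invariant_under_monotone_transform(self, rng):
        v = rng.normal(size=20)
        assert np.array_equal(median_split(v), median_split(np.exp(v)))


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate(records([1, 2, 3], [True, False, True]))
        assert np.array_equal(km.event_times, [1, 3])
        assert km.survival == pytest.approx([2 / 3, 0.0])
        assert np.array_equal(km.at_risk, [3, 1])

    def test_no_events_flat_curve(self):
        km = km_estimate(records([5, 8], [False, False]))
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_matches_lifelines(self, rng):
        for _ in range(15):
            t, e, _ = random_cohort(rng)
            if not e.any():
                continue
            km = km_estimate(records(t, e))
            kmf = KaplanMeierFitter().fit(t, e)
            expected = kmf.survival_function_.loc[km.event_times, "KM_estimate"].to_numpy()
            assert np.allclose(km.survival, expected, atol=1e-10)

    def test_order_invariance_and_monotonicity(self, rng):
        t, e, _ = random_cohort(rng)
        recs = records(t, e)
        km1 = km_estimate(recs)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        km2 = km_estimate(shuffled)
        assert np.array_equal(km1.event_times, km2.event_times)
        assert np.array_equal(km1.survival, km2.survival)
        assert np.all(np.diff(km1.survival) <= 1e-15)
        assert np.all((km1.survival >= -1e-15) & (km1.survival <= 1 + 1e-15))


class TestLogrank:
    def test_identical_groups_null(self):
        recs = records([3, 5, 7, 11], [True, True, False, True])
        chi2, p = logrank_test(recs, recs)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_hand_worked_six_subjects(self):
        # A: events at 1, 3; censored 5. B: events at 2, 4; censored 6.
        # Walking the risk sets: t=1 O-E=1-3/6, t=2 0-2/5, t=3 1-2/4,
        # t=4 0-1/3; V = sum d*(nA/n)*(1-nA/n)*(n-d)/(n-1) with d=1 each.
        a = records([1, 3, 5], [True, True, False], "a")
        b = records([2, 4, 6], [True, True, False], "b")
        o_minus_e = (1 - 3 / 6) + (0 - 2 / 5) + (1 - 2 / 4) + (0 - 1 / 3)
        v = (3 / 6) * (3 / 6) + (2 / 5) * (3 / 5) + (2 / 4) * (2 / 4) + (1 / 3) * (2 / 3)
        chi2, _ = logrank_test(a, b)
        assert chi2 == pytest.approx(o_minus_e**2 / v, abs=1e-12)

    def test_matches_lifelines(self, rng):
        for _ in range(15):
            t, e, x = random_cohort(rng)
            if not (e[x == 1].any() or e[x == 0].any()) or len(np.unique(x)) < 2:
                continue
            chi2, p = logrank_test(
                records(t[x == 1], e[x == 1]), records(t[x == 0], e[x == 0])
            )
            res = lifelines_logrank(t[x == 1], t[x == 0], e[x == 1], e[x == 0])
            assert chi2 == pytest.approx(res.test_statistic, abs=1e-10)
            assert p == pytest.approx(res.p_value, abs=1e-10)

    def test_no_events_rejected(self):
        a = records([1, 2], [False, False], "a")
        b = records([3, 4], [False, False], "b")
        with pytest.raises(ValidationError, match="event"):
            logrank_test(a, b)

    def test_equals_cox_score_test_without_ties(self, rng):
        t = rng.exponential(50.0, 50)  # continuous: no ties
        e = rng.random(50) < 0.8
        x = (rng.random(50) < 0.5).astype(float)
        recs = records(t, e)
        chi2, _ = logrank_test(
            [r for r, xi in zip(recs, x) if xi], [r for r, xi in zip(recs, x) if not xi]
        )
        assert chi2 == pytest.approx(cox_score_test(recs, x), rel=1e-8)


class TestCox:
    def test_null_covariate_recovers_hr_one(self):
        rng = np.random.default_rng(5)
        t, e, x = random_cohort(rng, n=400, round_times=False)
        fit = cox_univariate(records(t, e), x)
        assert fit.converged
        assert fit.ci_low < 1.0 < fit.ci_high
        assert abs(fit.log_hr) < 0.3

    def test_matches_lifelines_with_efron_ties(self, rng):
        checked = 0
        while checked < 10:
            t, e, x = random_cohort(rng, n=35)
            if e.sum() < 3 or len(np.unique(x)) < 2:
                continue
            fit = cox_univariate(records(t, e), x)
            if not fit.converged:
                continue
            cph = CoxPHFitter().fit(
                pd.DataFrame({"t": t, "e": e.astype(int), "x": x}),
                "t",
                "e",
                fit_options={"precision": 1e-12, "max_steps": 500},
            )
            assert fit.log_hr == pytest.approx(cph.params_["x"], abs=1e-6)
            assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)
            checked += 1

    def test_ci_and_hr_consistency(self, rng):
        t, e, x = random_cohort(rng, n=60)
        fit = cox_univariate(records(t, e), x)
        assert fit.hr == pytest.approx(np.exp(fit.log_hr))
        assert fit.ci_low == pytest.approx(np.exp(fit.log_hr - 1.96 * fit.se), rel=1e-3)
        assert fit.ci_low < fit.hr < fit.ci_high

    def test_monotone_likelihood_flagged_not_raised(self):
        # all events in the high group occur while every low subject is
        # still at risk and the low group never has an event: beta diverges
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.array([True, True, True, False, False, False])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = cox_univariate(records(t, e), x)
        assert not fit.converged
        assert not np.isfinite(fit.se)

    def test_constant_covariate_rejected(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([True, True, False, True])
        with pytest.raises(ValidationError, match="constant"):
            cox_univariate(records(t, e), np.ones(4))

    def test_recovers_planted_hazard_ratio(self):
        cfg = SimConfig(n_samples=500, planted_hr=0.5)
        counts, anns, truth = simulate_cohort(cfg, seed=1234)
        row = counts.row(truth.planted_survival_mirna)
        high = median_split(row)
        recs = [
            SurvivalRecord(a.sample_id, a.os_time, a.os_event) for a in anns
        ]
        fit = cox_univariate(recs, high.astype(float))
        assert 0.4 <= fit.hr <= 0.62


class TestSurvivalScreen:
    def _screen_inputs(self, seed, n=200, hr=0.5, n_mirnas=6):
        cfg = SimConfig(n_samples=n, planted_hr=hr)
        counts, anns, truth = simulate_cohort(cfg, seed=seed)
        sub_ids = counts.feature_ids[:n_mirnas]
        if truth.planted_survival_mirna not in sub_ids:
            sub_ids[-1] = truth.planted_survival_mirna
        return counts, anns, truth, sub_ids

    def test_planted_protective_mirna_has_smallest_logrank_p(self):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            counts, anns, truth, ids = self._screen_inputs(seed)
            # median-split screening is rank-based, so raw counts suffice here
            forest, _ = survival_screen(counts, anns, ids, endpoint="os")
            best = forest.loc[forest.p_logrank.idxmin(), "mirna_id"]
            wins += best == truth.planted_survival_mirna
        assert wins / n_seeds >= 0.9

    def test_forest_table_shape_and_km_output(self):
        counts, anns, truth, ids = self._screen_inputs(3, n=60)
        forest, curves = survival_screen(counts, anns, ids, endpoint="pfs")
        assert list(forest.mirna_id) == ids
        assert set(curves) == set(ids)
        for strata in curves.values():
            assert set(strata) == {"high", "low"}
        assert (forest.n_high + forest.n_low == 60).all()

    def test_missing_endpoint_samples_dropped(self):
        counts, anns, truth, ids = self._screen_inputs(4, n=30)
        anns[0] = SampleAnnotation(anns[0].sample_id, purity=anns[0].purity,
                                   group=anns[0].group)  # no survival fields
        forest, _ = survival_screen(counts, anns, ids[:2], endpoint="os")
        assert (forest.n_high + forest.n_low == 29).all()

    def test_absent_mirna_rejected(self):
        counts, anns, truth, ids = self._screen_inputs(5, n=30)
        with pytest.raises(ValidationError, match="absent"):
            survival_screen(counts, anns, ["nope"], endpoint="os")
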