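"""Pearson, Student's t, Kaplan-Meier, and log-rank against independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats as spstats

from mirip import (
    DegenerateInputError,
    MissingDataError,
    SampleSizeError,
    km_estimate,
    logrank_test,
    pearson_test,
    student_t_test,
)


class TestPearson:
    def test_perfect_linearity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = pearson_test(x, [2 * v + 1 for v in x])
        assert res.estimate == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula_and_scipy(self, rng):
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        res = pearson_test(x, y)
        # textbook recomputation
        r = float(np.sum((x - x.mean()) * (y - y.mean()))
                  / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        t = r * math.sqrt(8 / (1 - r * r))
        p = 2 * spstats.t.sf(abs(t), 8)
        assert res.estimate == pytest.approx(r, abs=1e-10)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        # independent implementation
        sp_r, sp_p = spstats.pearsonr(x, y)
        assert res.estimate == pytest.approx(sp_r, abs=1e-10)
        assert res.p_value == pytest.approx(sp_p, abs=1e-10)

    def test_scipy_agreement_over_random_inputs(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = pearson_test(x, y)
            sp_r, sp_p = spstats.pearsonr(x, y)
            assert res.estimate == pytest.approx(sp_r, abs=1e-10)
            assert res.p_value == pytest.approx(sp_p, abs=1e-8)

    def test_errors(self):
        with pytest.raises(SampleSizeError):
            pearson_test([1, 2], [3, 4])
        with pytest.raises(DegenerateInputError):
            pearson_test([1, 1, 1], [1, 2, 3])


class TestStudentT:
    def test_identical_groups(self):
        res = student_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_pooled_variance(self):
        res = student_t_test([1, 2, 3], [4, 5, 6])
        # means 2 and 5, each sample variance 1, pooled 1, se = sqrt(2/3)
        t = -3.0 / math.sqrt(2.0 / 3.0)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == 4.0
        assert res.p_value == pytest.approx(2 * spstats.t.sf(abs(t), 4), abs=1e-10)

    def test_matches_scipy_equal_variance(self, rng):
        for _ in range(100):
            a = rng.normal(size=int(rng.integers(2, 20)))
            b = rng.normal(loc=0.5, size=int(rng.integers(2, 20)))
            res = student_t_test(a, b)
            sp = spstats.ttest_ind(a, b, equal_var=True)
            assert res.statistic == pytest.approx(sp.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(sp.pvalue, abs=1e-10)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=6)
        r1, r2 = student_t_test(a, b), student_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_errors(self):
        with pytest.raises(SampleSizeError):
            student_t_test([1.0], [1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            student_t_test([1.0, 1.0], [1.0, 1.0])


def _random_survival(rng, n):
    times = rng.exponential(10.0, size=n) + 1e-3
    events = rng.random(n) < 0.7
    return times, events


class TestKaplanMeier:
    def test_all_events(self):
        curve = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        assert curve.times == (1.0, 2.0, 3.0)
        assert curve.survival == pytest.approx((2 / 3, 1 / 3, 0.0))
        assert curve.at_risk == (3, 2, 1)

    def test_no_events_constant_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [False, False, False])
        assert curve.times == ()
        assert curve.survival_at(5.0) == 1.0

    def test_censoring_shrinks_risk_set(self):
        curve = km_estimate([1.0, 2.0, 3.0], [True, False, True])
        assert curve.survival == pytest.approx((2 / 3, 0.0))
        assert curve.at_risk == (3, 1)

    def test_monotone_in_unit_interval(self, rng):
        for _ in range(200):
            times, events = _random_survival(rng, int(rng.integers(1, 50)))
            if not events.any():
                continue
            curve = km_estimate(times, events)
            s = np.array(curve.survival)
            assert np.all(s >= -1e-15) and np.all(s <= 1.0 + 1e-15)
            assert np.all(np.diff(s) <= 1e-15)
            assert np.all(np.diff(np.array(curve.at_risk)) < 0)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        for _ in range(50):
            times, events = _random_survival(rng, 40)
            curve = km_estimate(times, events)
            kmf = KaplanMeierFitter().fit(times, events)
            for t, s in zip(curve.times, curve.survival):
                assert s == pytest.approx(
                    float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-6
                )

    def test_empty_raises(self):
        with pytest.raises(MissingDataError):
            km_estimate([], [])


def _naive_logrank(ta, ea, tb, eb):
    """Spreadsheet-style recomputation over the per-time 2x2 tables."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, bool)
    tb, eb = np.asarray(tb, float), np.asarray(eb, bool)
    all_event_times = sorted(set(ta[ea]) | set(tb[eb]))
    o_e, v = 0.0, 0.0
    for t in all_event_times:
        n1 = (ta >= t).sum()
        n2 = (tb >= t).sum()
        d1 = ((ta == t) & ea).sum()
        d2 = ((tb == t) & eb).sum()
        n, d = n1 + n2, d1 + d2
        o_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_e * o_e / v


class TestLogrank:
    def test_identical_arms(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, True]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_arm_relabeling_symmetry(self, rng):
        ta, ea = _random_survival(rng, 15)
        tb, eb = _random_survival(rng, 20)
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_toy_six_subject_hand_oracle(self):
        ta, ea = [1.0, 3.0, 5.0], [True, True, False]
        tb, eb = [2.0, 4.0, 6.0], [True, True, True]
        res = logrank_test(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(
            _naive_logrank(ta, ea, tb, eb), abs=1e-8
        )

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(50):
            ta, ea = _random_survival(rng, int(rng.integers(5, 40)))
            tb, eb = _random_survival(rng, int(rng.integers(5, 40)))
            if not (ea.any() or eb.any()):
                continue
            res = logrank_test(ta, ea, tb, eb)
            ll = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert res.statistic == pytest.approx(ll.test_statistic, abs=1e-6)
            assert res.p_value == pytest.approx(ll.p_value, abs=1e-6)

    def test_no_events_raises(self):
        with pytest.raises(DegenerateInputError):
            logrank_test([1.0], [False], [2.0], [False])

    def test_empty_arm_raises(self):
        with pytest.raises(MissingDataError):
            logrank_test([], [], [1.0], [True])
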