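"""Log-rank test and maximally selected cut-point search."""

import numpy as np
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from tilquant.cutpoint import (
    NoAdmissibleCutError,
    StatisticUndefinedError,
    apply_cutpoint,
    find_optimal_cutpoint,
    logrank_test,
    miller_siegmund_pvalue,
)


def brute_force_logrank(times_a, events_a, times_b, events_b):
    """Independent O/E/V tabulation over distinct event times."""
    times = np.r_[times_a, times_b]
    events = np.r_[events_a, events_b].astype(bool)
    in_a = np.r_[np.ones(len(times_a)), np.zeros(len(times_b))].astype(bool)
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n, na = at_risk.sum(), (at_risk & in_a).sum()
        d = (events & (times == t)).sum()
        da = (events & (times == t) & in_a).sum()
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_event_table(self):
        # A: events at 1 and 2; B: censored at 3 and 3.
        chi2, _ = logrank_test([1.0, 2.0], [1, 1], [3.0, 3.0], [0, 0])
        # Risk sets: t=1 -> (nA=2, n=4, d=1); t=2 -> (nA=1, n=3, d=1).
        # sum(O-E) = (1 - 2/4) + (1 - 1/3) = 7/6
        # sum(V) = (2/4)(2/4) + (1/3)(2/3) = 17/36
        assert chi2 == pytest.approx((7 / 6) ** 2 / (17 / 36), abs=1e-12)
        assert chi2 == pytest.approx(
            brute_force_logrank([1.0, 2.0], [1, 1], [3.0, 3.0], [0, 0])
        )

    def test_agrees_with_established_implementation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(30, 100)
            t1 = rng.exponential(1.0, n)
            t2 = rng.exponential(1.4, n)
            e1 = rng.random(n) < 0.8
            e2 = rng.random(n) < 0.8
            if e1.sum() + e2.sum() == 0:
                continue
            chi2, p = logrank_test(t1, e1, t2, e2)
            ref = lifelines_logrank(t1, t2, e1, e2)
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_no_events_undefined(self):
        with pytest.raises(StatisticUndefinedError):
            logrank_test([1.0, 2.0], [0, 0], [3.0], [0])


class TestFindOptimalCutpoint:
    def _cohort_with_changepoint(self):
        # values 1..10 (x3 replicates for n >= 20); events with short times
        # only among values > 5.
        values = np.tile(np.arange(1.0, 11.0), 3)
        times = np.where(values > 5, 1.0 + values / 10, 50.0 + values)
        events = (values > 5).astype(int)
        return values, times, events

    def test_recovers_obvious_threshold(self):
        values, times, events = self._cohort_with_changepoint()
        res = find_optimal_cutpoint(values, times, events, 0.1)
        assert res.threshold == pytest.approx(5.5)
        assert res.n_low + res.n_high == len(values)

    def test_scan_equals_exhaustive_brute_force(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 30, 60)
        times = rng.exponential(20.0, 60)
        events = (rng.random(60) < 0.7).astype(int)
        res = find_optimal_cutpoint(values, times, events, 0.1)
        uniq = np.unique(values)
        best = (-1.0, None)
        scan = {}
        for c in (uniq[:-1] + uniq[1:]) / 2:
            high = values >= c
            if min(high.sum(), (~high).sum()) < np.ceil(0.1 * 60):
                continue
            chi2 = brute_force_logrank(
                times[high], events[high], times[~high], events[~high]
            )
            scan[c] = chi2
            if chi2 > best[0] + 1e-12:
                best = (chi2, c)
        assert res.chi_square == pytest.approx(best[0], abs=1e-8)
        assert res.threshold == pytest.approx(best[1])
        for cand, chi2 in res.scan:
            assert chi2 == pytest.approx(scan[cand], abs=1e-8)

    def test_chi_square_is_scan_maximum(self):
        values, times, events = self._cohort_with_changepoint()
        res = find_optimal_cutpoint(values, times, events, 0.1)
        assert res.chi_square == pytest.approx(max(c for _, c in res.scan))

    def test_constant_values_rejected(self):
        with pytest.raises(NoAdmissibleCutError):
            find_optimal_cutpoint(
                np.ones(30), np.arange(1.0, 31.0), np.ones(30, dtype=int), 0.1
            )

    def test_corrected_p_not_smaller_than_raw(self):
        values, times, events = self._cohort_with_changepoint()
        res = find_optimal_cutpoint(values, times, events, 0.1)
        assert res.p_corrected >= res.p_raw

    def test_monotone_transform_preserves_partition(self):
        values, times, events = self._cohort_with_changepoint()
        r1 = find_optimal_cutpoint(values, times, events, 0.1)
        r2 = find_optimal_cutpoint(np.exp(values / 4), times, events, 0.1)
        np.testing.assert_array_equal(
            apply_cutpoint(values, r1.threshold),
            apply_cutpoint(np.exp(values / 4), r2.threshold),
        )

    def test_permutation_correction_seeded(self):
        values, times, events = self._cohort_with_changepoint()
        r1 = find_optimal_cutpoint(
            values, times, events, 0.1, correction="permutation",
            n_permutations=100, seed=7,
        )
        r2 = find_optimal_cutpoint(
            values, times, events, 0.1, correction="permutation",
            n_permutations=100, seed=7,
        )
        assert 0 < r1.p_corrected <= 1
        assert r1.p_corrected == r2.p_corrected

    def test_miller_siegmund_properties(self):
        # Decreasing in the statistic; wider scan band -> larger correction.
        p1 = miller_siegmund_pvalue(8.0, 0.1, 0.9)
        p2 = miller_siegmund_pvalue(12.0, 0.1, 0.9)
        p3 = miller_siegmund_pvalue(8.0, 0.02, 0.98)
        assert p2 < p1 < p3


class TestApplyCutpoint:
    def test_boundary_value_is_high(self):
        labels = apply_cutpoint([10.0, 13.2, 20.0], 13.2)
        np.testing.assert_array_equal(labels, [False, True, True])

    def test_all_below_threshold(self):
        assert not apply_cutpoint([1.0, 2.0, 3.0], 10.0).any()

    def test_matches_elementwise_comparison(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 30, 100)
        np.testing.assert_array_equal(
            apply_cutpoint(vals, 13.2), np.array([v >= 13.2 for v in vals])
        )

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_cutpoint([1.0], np.nan)
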