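"""Selection events and truncation sets.

The central correctness property: for every rule, the interval algebra must
reproduce the raw event predicate pointwise — the predicate applies the
rule to the stage-1 vector implied by a candidate stage-2 value and knows
nothing about intervals.
"""

import math

import numpy as np
import pytest

from umvcue import EventViolationError, SelectionRule, SnpSummary, StudyData, check_event
from umvcue.selection import (
    event_predicate,
    implied_stage1,
    truncation_effect,
    truncation_for_rule,
    truncation_p_one,
    truncation_p_two,
)

from conftest import random_instance


def study_of(xs, sigmas, ys=None, taus=None, V=None):
    K = len(xs)
    ys = ys if ys is not None else [0.0] * K
    taus = taus if taus is not None else [1.0] * K
    snps = tuple(
        SnpSummary(f"s{i}", xs[i], sigmas[i], ys[i], taus[i]) for i in range(K)
    )
    return StudyData(snps, V)


class TestSelectionRule:
    def test_thresholds(self):
        assert SelectionRule("effect").threshold == -math.inf
        one = SelectionRule("p_one_sided", 0.05)
        assert one.threshold == pytest.approx(1.6449, abs=1e-4)
        two = SelectionRule("p_two_sided", 0.05)
        assert two.threshold == pytest.approx(1.9600, abs=1e-4)

    def test_keys(self):
        x = np.array([-2.0, 1.0])
        s = np.array([1.0, 2.0])
        assert np.allclose(SelectionRule("effect").keys(x, s), x)
        assert np.allclose(SelectionRule("p_one_sided").keys(x, s), [-2.0, 0.5])
        assert np.allclose(SelectionRule("p_two_sided").keys(x, s), [2.0, 0.5])


class TestCheckEvent:
    def test_fixture_passes_weak_threshold(self, parkes, parkes_rule):
        assert check_event(parkes, parkes_rule) is parkes

    def test_fixture_fails_genomewide_threshold(self, parkes):
        # printed rank-11 z is 4.06, below the 1e-7 two-sided cutoff of 5.33
        with pytest.raises(EventViolationError, match="threshold"):
            check_event(parkes, SelectionRule("p_two_sided", 1e-7))

    def test_wrong_order_names_pair(self):
        st = study_of([1.0, 2.0], [1.0, 1.0])
        with pytest.raises(EventViolationError, match="s0.*s1"):
            check_event(st, SelectionRule("effect"))

    def test_single_below_threshold(self):
        st = study_of([1.0], [1.0])
        with pytest.raises(EventViolationError):
            check_event(st, SelectionRule("p_one_sided", 1e-4))


class TestImpliedStage1:
    def test_observed_y_recovers_observed_x(self, parkes, parkes_rule):
        from umvcue import sufficient_stats

        j = 3
        z = sufficient_stats(parkes, j)
        xs = implied_stage1(parkes.y[j - 1], z, parkes.V[:, j - 1], parkes.tau[j - 1])
        assert np.allclose(xs, parkes.x, atol=1e-12)

    def test_independence_leaves_others_constant(self):
        z = np.array([1.0, 2.0, 3.0])
        v = np.array([0.5, 0.0, 0.0])
        for y in (-3.0, 0.0, 7.0):
            xs = implied_stage1(y, z, v, 1.3)
            assert xs[1] == 2.0 and xs[2] == 3.0

    def test_round_trip_z(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=4)
        v = rng.normal(size=4)
        tau = 0.8
        y = 1.7
        xs = implied_stage1(y, z, v, tau)
        assert np.allclose(xs + v / tau**2 * y, z, atol=1e-12)


class TestEventPredicate:
    def test_observed_point_true(self, parkes, parkes_rule):
        from umvcue import sufficient_stats

        for j in (1, 5, 11):
            z = sufficient_stats(parkes, j)
            assert event_predicate(
                parkes.y[j - 1], z, parkes.V[:, j - 1], parkes.sigma,
                parkes.tau[j - 1], parkes_rule,
            )

    def test_far_y_eventually_false(self):
        # independence, effect ordering: moving y drags X_1(y) past X_2
        z = np.array([1.0, 0.5])
        v = np.array([1.0, 0.0])
        rule = SelectionRule("effect")
        sig = np.array([1.0, 1.0])
        assert event_predicate(0.0, z, v, sig, 1.0, rule)
        assert not event_predicate(10.0, z, v, sig, 1.0, rule)

    def test_single_candidate_effect_always_true(self):
        rule = SelectionRule("effect")
        for y in (-50.0, 0.0, 50.0):
            assert event_predicate(y, np.array([0.3]), np.array([1.0]),
                                   np.array([1.0]), 1.0, rule)


class TestTruncationClosedForms:
    def test_effect_independence_k2(self):
        # diagonal V, j=1: single lower-bounded... upper-bounded interval
        # [tau^2 (Z1 - Z2)/sigma1^2 boundary], matching the independence case
        z = np.array([2.0, 0.5])
        sig1, tau = 0.7, 1.1
        v = np.array([sig1**2, 0.0])
        ts = truncation_effect(z, v, tau)
        assert len(ts.intervals) == 1
        iv = ts.intervals[0]
        assert iv.hi == pytest.approx(tau**2 * (z[0] - z[1]) / sig1**2)
        assert iv.lo == -math.inf

    def test_single_candidate_unbounded(self):
        ts = truncation_effect(np.array([1.0]), np.array([0.25]), 1.0)
        assert ts.intervals[0].lo == -math.inf
        assert ts.intervals[0].hi == math.inf

    def test_two_sided_k1_c0_full_line(self):
        ts = truncation_p_two(np.array([1.0]), np.array([0.25]),
                              np.array([0.5]), 1.0, 0.0)
        assert ts.intervals[0].lo == -math.inf and ts.intervals[0].hi == math.inf

    def test_one_sided_equal_sigmas_reduces_to_effect(self):
        # with all sigmas equal and no threshold, X/sigma ordering is the
        # effect ordering, so the truncation sets must coincide
        rng = np.random.default_rng(3)
        z = np.sort(rng.normal(size=4))[::-1].copy()
        v = rng.normal(scale=0.3, size=4)
        v[0] = 0.5  # target variance slot, any consistent values work here
        ts_eff = truncation_effect(z, v, 0.9)
        ts_one = truncation_p_one(z, v, np.full(4, 1.0), 0.9, -math.inf)
        assert len(ts_eff.intervals) == len(ts_one.intervals)
        for a, b in zip(ts_eff.intervals, ts_one.intervals):
            assert a.lo == pytest.approx(b.lo, rel=1e-12)
            assert a.hi == pytest.approx(b.hi, rel=1e-12)


@pytest.mark.parametrize("ordering", ["effect", "p_one_sided", "p_two_sided"])
@pytest.mark.parametrize("seed", range(8))
def test_truncation_matches_predicate_on_grid(ordering, seed):
    """The interval algebra and the raw predicate agree on a fine grid
    (the central correctness property, |rho| up to 0.95, K <= 6)."""
    rng = np.random.default_rng(1000 * seed + 17)
    K = int(rng.integers(1, 7))
    study, rule, j = random_instance(rng, K, ordering)
    jj = j - 1
    from umvcue import sufficient_stats

    z = sufficient_stats(study, j)
    vcol = study.V[:, jj]
    tau_j = study.tau[jj]
    ts = truncation_for_rule(z, vcol, study.sigma, tau_j, rule)
    assert ts.contains(study.y[jj], tol=1e-9)

    m = study.y[jj]
    span = 20.0 * max(tau_j, study.sigma[jj])
    grid = np.linspace(m - span, m + span, 2000)
    # keep clear of interval endpoints where predicate and closed-interval
    # membership may legitimately differ by one ulp
    edges = [e for iv in ts.intervals for e in (iv.lo, iv.hi) if math.isfinite(e)]
    for y in grid:
        if any(abs(y - e) < 1e-7 * span for e in edges):
            continue
        assert ts.contains(y) == event_predicate(
            y, z, vcol, study.sigma, tau_j, rule
        ), f"mismatch at y={y}"


def test_truncation_intervals_canonical(parkes, parkes_rule):
    from umvcue import sufficient_stats

    for j in range(1, parkes.K + 1):
        z = sufficient_stats(parkes, j)
        ts = truncation_for_rule(
            z, parkes.V[:, j - 1], parkes.sigma, parkes.tau[j - 1], parkes_rule
        )
        assert ts.M >= 1
        for a, b in zip(ts.intervals, ts.intervals[1:]):
            assert a.hi < b.lo
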