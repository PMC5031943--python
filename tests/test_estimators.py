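"""Estimator correctness: sufficient statistics, the truncated-normal mean,
the bivariate closed form, and equivalence of all code paths with the
quadrature oracle."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from umvcue import (
    ConditionalLaw,
    MassUnderflowError,
    SelectionRule,
    SnpSummary,
    StudyData,
    mle,
    sufficient_stats,
    truncnorm_mean,
    umvcue,
    umvcue_bivariate_effect,
    umvcue_independent,
)
from umvcue.intervals import Interval, IntervalSet
from umvcue.oracle import oracle_conditional_mean
from umvcue.selection import TruncationSet

from conftest import random_instance


def ts_of(*pairs):
    return TruncationSet(IntervalSet([Interval(a, b) for a, b in pairs]))


class TestSufficientStats:
    def test_independence_shifts_only_target(self, parkes):
        z = sufficient_stats(parkes, 1)
        s0 = parkes.snps[0]
        assert z[0] == pytest.approx(
            s0.x + s0.sigma**2 / s0.tau**2 * s0.y, rel=1e-12
        )
        assert np.allclose(z[1:], parkes.x[1:], atol=1e-15)

    def test_fixture_value(self, parkes):
        # ln 1.55 + (0.0591/0.0766)^2 * ln 1.16
        # 4-dp intermediate rounding of the converted inputs shifts the
        # printed arithmetic by ~1.5e-4
        assert sufficient_stats(parkes, 1)[0] == pytest.approx(0.5266, abs=5e-4)

    def test_infinite_tau_limit(self, parkes):
        snps = tuple(
            SnpSummary(s.snp_id, s.x, s.sigma, s.y, 1e6) for s in parkes.snps
        )
        st = StudyData(snps)
        assert np.allclose(sufficient_stats(st, 1), st.x, atol=1e-9)


class TestTruncnormMean:
    LAW = ConditionalLaw(m=0.3, s=0.7)

    def test_untruncated_returns_mean(self):
        v, mass = truncnorm_mean(self.LAW, ts_of((-math.inf, math.inf)))
        assert v == pytest.approx(self.LAW.m, abs=1e-15)
        assert mass == pytest.approx(1.0)

    def test_half_normal(self):
        v, mass = truncnorm_mean(self.LAW, ts_of((self.LAW.m, math.inf)))
        assert v == pytest.approx(self.LAW.m + self.LAW.s * math.sqrt(2 / math.pi))
        assert mass == pytest.approx(0.5)

    def test_symmetric_union_is_unbiased(self):
        law = ConditionalLaw(m=0.0, s=1.0)
        v, mass = truncnorm_mean(law, ts_of((-3.0, -1.0), (1.0, 3.0)))
        assert v == pytest.approx(0.0, abs=1e-15)
        assert mass == pytest.approx(2 * (norm.cdf(3) - norm.cdf(1)))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        m, s = rng.normal(), rng.uniform(0.2, 2.0)
        law = ConditionalLaw(m, s)
        edges = np.sort(rng.normal(m, 3 * s, size=4))
        ts = ts_of((edges[0], edges[1]), (edges[2], edges[3]))
        v, mass = truncnorm_mean(law, ts)
        num = den = 0.0
        for iv in ts.intervals:
            num += integrate.quad(
                lambda y: y * norm.pdf(y, m, s), iv.lo, iv.hi, epsabs=1e-14
            )[0]
            den += integrate.quad(
                lambda y: norm.pdf(y, m, s), iv.lo, iv.hi, epsabs=1e-14
            )[0]
        assert v == pytest.approx(num / den, rel=1e-8)
        assert mass == pytest.approx(den, rel=1e-8)

    def test_deep_tail_stable(self):
        # interval 40+ SDs out: naive Phi differences underflow to 0/0, the
        # scaled path must give the classic a + s/W tail behaviour
        law = ConditionalLaw(m=0.0, s=1.0)
        a = 40.0
        v, mass = truncnorm_mean(law, ts_of((a, math.inf)))
        assert math.isfinite(v)
        assert v == pytest.approx(a + 1 / a, rel=1e-3)
        assert mass == 0.0  # honest float underflow; value still exact

    def test_zero_width_interval_raises(self):
        with pytest.raises(MassUnderflowError):
            truncnorm_mean(self.LAW, ts_of((1.0, 1.0)))


class TestMle:
    def test_fixture_top_snp(self, parkes):
        s = parkes.snps[0]
        assert math.exp(mle(s.x, s.sigma, s.y, s.tau)) == pytest.approx(1.39, abs=0.005)

    def test_fixture_second_snp(self, parkes):
        # printed value 1.37; 2-dp-rounded CI inputs land at 1.364
        s = parkes.snps[1]
        assert math.exp(mle(s.x, s.sigma, s.y, s.tau)) == pytest.approx(1.37, abs=0.01)

    def test_equal_ses_give_arithmetic_mean(self):
        assert mle(0.4, 0.1, 0.2, 0.1) == pytest.approx(0.3, rel=1e-12)


class TestBivariateClosedForm:
    def test_degenerate_branch_equals_mle_exactly(self):
        s1, s2 = 0.05, 0.1
        rho = s1 / s2
        val = umvcue_bivariate_effect(0.12, 0.08, s1, s2, rho, 0.09, 0.07)
        assert val == mle(0.12, s1, 0.09, 0.07)  # bitwise equal

    @pytest.mark.parametrize("rho", [0.0, -0.6, 0.6, 0.9])
    def test_matches_general_path(self, rho):
        rng = np.random.default_rng(42)
        for _ in range(25):
            s1, s2 = rng.uniform(0.3, 1.5, 2)
            tau = rng.uniform(0.3, 1.5)
            x2 = rng.normal()
            x1 = x2 + rng.uniform(0.05, 2.0)
            y = rng.normal(x1, tau)
            direct = umvcue_bivariate_effect(x1, x2, s1, s2, rho, y, tau)
            V = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
            st = StudyData(
                (SnpSummary("a", x1, s1, y, tau), SnpSummary("b", x2, s2, 0.0, 1.0)),
                V,
            )
            general = umvcue(st, SelectionRule("effect"), 1).value
            assert direct == pytest.approx(general, rel=1e-10, abs=1e-10)

    def test_event_violation_rejected(self):
        with pytest.raises(Exception, match="x1 > x2"):
            umvcue_bivariate_effect(0.1, 0.2, 0.1, 0.1, 0.0, 0.1, 0.1)


class TestUmvcueGeneral:
    @pytest.mark.parametrize("ordering", ["effect", "p_one_sided", "p_two_sided"])
    @pytest.mark.parametrize("seed", range(10))
    def test_equals_quadrature_oracle(self, ordering, seed):
        rng = np.random.default_rng(20_000 + 131 * seed)
        K = int(rng.integers(1, 7))
        study, rule, j = random_instance(rng, K, ordering)
        val = umvcue(study, rule, j).value
        orc = oracle_conditional_mean(study, rule, j)
        scale = max(abs(val), study.tau[j - 1])
        assert abs(val - orc) <= 1e-6 * scale

    def test_diagonal_reduction_consistency(self, parkes, parkes_rule):
        # with a diagonal V, the general path and the forced-independence
        # path must agree identically
        for j in (1, 5, 11):
            a = umvcue(parkes, parkes_rule, j).value
            b = umvcue_independent(parkes, parkes_rule, j).value
            assert a == pytest.approx(b, rel=1e-14)

    def test_fixture_deep_tail_is_finite(self, parkes, parkes_rule):
        # the fixture's z-scores (up to 7.4) sit where naive arithmetic
        # underflows; estimates and masses must come out finite and sane
        for j in range(1, parkes.K + 1):
            res = umvcue(parkes, parkes_rule, j)
            assert math.isfinite(res.value)
            assert 0.0 < res.mass <= 1.0
            assert 0.9 < res.odds_ratio < 1.7

    def test_information_limits(self):
        # tau -> 0: stage 2 dominates, estimate -> y; tau large: strong
        # correction away from the selected x toward the truncation
        rng = np.random.default_rng(5)
        x = np.array([1.2, 0.6])
        sig = np.array([0.5, 0.5])
        y_obs = 0.9
        prev = None
        for tau in (1e-3, 0.1, 0.5, 2.0):
            st = StudyData(
                (
                    SnpSummary("a", x[0], sig[0], y_obs, tau),
                    SnpSummary("b", x[1], sig[1], 0.0, 1.0),
                )
            )
            val = umvcue(st, SelectionRule("effect"), 1).value
            if prev is None:
                assert val == pytest.approx(y_obs, abs=1e-4)
            prev = val

    def test_vacuous_truncation_approaches_mle(self):
        # single candidate far above a one-sided threshold: conditioning is
        # nearly vacuous, so the UMVCUE collapses onto the MLE
        st = StudyData((SnpSummary("a", 1.0, 0.1, 0.9, 0.1),))
        rule = SelectionRule("p_one_sided", 0.5)
        res = umvcue(st, rule, 1)
        assert res.mass == pytest.approx(1.0, abs=1e-6)
        assert res.value == pytest.approx(mle(1.0, 0.1, 0.9, 0.1), abs=1e-6)
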