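"""Chakraborti-Li and Bland-Altman central-t approximations."""

import math

import pytest
from hypothesis import given, strategies as st

import perctest as pt
from perctest._power import pivotal_critical

METHODS = [pt.Method.CHAKRABORTI_LI, pt.Method.BLAND_ALTMAN]


class TestVarianceFactors:
    def test_median_collapses(self):
        fac = pt.variance_factors(25, pt.PercentileSpec(0.5))
        assert fac.m == pytest.approx(1.0, abs=1e-14)
        assert fac.b == pytest.approx(1.0, abs=1e-14)

    def test_dissolution_values(self):
        # frozen from direct evaluation of m = 1 + n z^2 (c^2 - 1) and
        # b = 1 + z^2/2 at n=15, p=0.9
        fac = pt.variance_factors(15, pt.PercentileSpec(0.9))
        assert fac.b == pytest.approx(1.8212, abs=5e-5)
        assert fac.m == pytest.approx(1.8950, abs=5e-5)

    @given(n=st.integers(2, 200), p=st.floats(0.05, 0.95))
    def test_positivity(self, n, p):
        fac = pt.variance_factors(n, pt.PercentileSpec(p))
        assert fac.m > 0
        assert fac.b >= 1


class TestWorkedExample:
    def test_difference_statistics(self, dissolution, diff_spec):
        res_m = pt.test_percentile_approx("chakraborti_li", dissolution, diff_spec)
        res_b = pt.test_percentile_approx("bland_altman", dissolution, diff_spec)
        assert res_m.statistic == pytest.approx(2.0857, abs=5e-5)
        assert res_b.statistic == pytest.approx(2.0614, abs=5e-5)
        assert res_m.critical_value[1] == pytest.approx(2.1448, abs=5e-5)
        assert not res_m.reject and not res_b.reject  # the exact test rejects here
        assert res_m.ncp is None

    def test_noninferiority_agrees_with_exact(self, dissolution):
        spec = pt.HypothesisSpec("noninferiority_greater", p=0.9, theta0=50.8379)
        for method in METHODS:
            res = pt.test_percentile_approx(method, dissolution, spec)
            assert res.critical_value == pytest.approx(1.7613, abs=5e-5)
            assert res.reject

    def test_equivalence_pairs(self, dissolution, eq_spec):
        res_m = pt.test_equivalence_approx("chakraborti_li", dissolution, eq_spec)
        res_b = pt.test_equivalence_approx("bland_altman", dissolution, eq_spec)
        assert res_m.statistic == pytest.approx((2.8845, -2.2700), abs=5e-5)
        assert res_b.statistic == pytest.approx((2.8761, -2.3817), abs=5e-5)
        assert res_m.critical_value == pytest.approx((1.7613, -1.7613), abs=5e-5)
        assert res_m.reject and res_b.reject


class TestMedianCollapse:
    """At p = 0.5 all three methods are the same test."""

    @given(
        mean=st.floats(-5, 5),
        sd=st.floats(0.1, 4),
        n=st.integers(2, 80),
        theta0=st.floats(-6, 6),
    )
    def test_statistics_and_decisions_coincide(self, mean, sd, n, theta0):
        sample = pt.SummaryStats(n, mean, sd)
        spec = pt.HypothesisSpec("difference", p=0.5, theta0=theta0)
        exact = pt.test_percentile_exact(sample, spec)
        for method in METHODS:
            approx = pt.test_percentile_approx(method, sample, spec)
            assert approx.statistic == pytest.approx(exact.statistic, rel=1e-12, abs=1e-12)
            assert approx.reject == exact.reject

    @pytest.mark.parametrize("test_type", ["difference", "noninferiority_greater",
                                           "noninferiority_less", "equivalence"])
    def test_powers_coincide(self, test_type):
        kw = (
            dict(theta_t=0.1, delta=0.6)
            if test_type == "equivalence"
            else dict(theta0=0.1)
        )
        scn = pt.PowerScenario(mu=0.4, sigma=1.0, p=0.5, n=30, **kw)
        ref = pt.power_exact(test_type, scn)
        for method in METHODS:
            assert pt.power_approx(method, test_type, scn) == pytest.approx(ref, abs=1e-12)

    def test_sample_sizes_coincide(self):
        scn = pt.PowerScenario(mu=0.4, sigma=1.0, p=0.5, theta0=0.0)
        ns = {
            m: pt.required_sample_size(m, "difference", scn).n_required
            for m in pt.Method
        }
        assert len(set(ns.values())) == 1


class TestPivotalIdentity:
    """Rejection via the standardized estimator equals rejection via the
    pivotal statistic against the shifted critical value — the algebra
    behind the approximate power functions."""

    @pytest.mark.parametrize("method", METHODS)
    @given(
        mean=st.floats(-5, 5),
        sd=st.floats(0.1, 4),
        n=st.integers(3, 60),
        p=st.floats(0.1, 0.9),
        theta0=st.floats(-6, 6),
    )
    def test_difference(self, method, mean, sd, n, p, theta0):
        sample = pt.SummaryStats(n, mean, sd)
        spec = pt.HypothesisSpec("difference", p=p, theta0=theta0)
        res = pt.test_percentile_approx(method, sample, spec)
        t_pivot = (mean - theta0) / (sd / math.sqrt(n))
        lo = pivotal_critical(method, spec.alpha / 2, n, p)
        hi = pivotal_critical(method, 1 - spec.alpha / 2, n, p)
        assert res.reject == (t_pivot < lo or t_pivot > hi)

    @pytest.mark.parametrize("method", METHODS)
    @given(
        mean=st.floats(-5, 5),
        sd=st.floats(0.1, 4),
        n=st.integers(3, 60),
        p=st.floats(0.1, 0.9),
        theta_t=st.floats(-5, 5),
        delta=st.floats(0.1, 3),
    )
    def test_equivalence(self, method, mean, sd, n, p, theta_t, delta):
        sample = pt.SummaryStats(n, mean, sd)
        spec = pt.HypothesisSpec("equivalence", p=p, theta_t=theta_t, delta=delta)
        res = pt.test_equivalence_approx(method, sample, spec)
        se = sd / math.sqrt(n)
        lo = pivotal_critical(method, 1 - spec.alpha, n, p)
        hi = pivotal_critical(method, spec.alpha, n, p)
        expected = ((mean - theta_t + delta) / se > lo) and ((mean - theta_t - delta) / se < hi)
        assert res.reject == expected


class TestApproxPower:
    def test_difference_power_is_probability_and_tends_to_one(self):
        for method in METHODS:
            powers = [
                pt.power_approx(
                    method,
                    "difference",
                    pt.PowerScenario(mu=0.6, sigma=1.0, p=0.9, n=n,
                                     theta0=pt.z_quantile(0.9)),
                )
                for n in (10, 40, 160, 640)
            ]
            assert all(0 <= w <= 1 for w in powers)
            assert powers[-1] > 0.99

    def test_bland_altman_two_sided_includes_upper_tail(self):
        # The two-sided power must dominate each of its one-sided pieces;
        # this fails if the second term is taken as a lower-tail
        # probability (a sign slip easily made in the Bland-Altman form).
        scn = pt.PowerScenario(mu=0.6, sigma=1.0, p=0.3, n=28,
                               theta0=pt.z_quantile(0.3), alpha=0.05)
        two = pt.power_approx("bland_altman", "difference", scn)
        hi = pivotal_critical(pt.Method.BLAND_ALTMAN, 1 - 0.025, 28, 0.3)
        upper = float(pt.nct_sf(hi, 27, scn.ncp))
        assert two >= upper > 0.5

    @pytest.mark.parametrize("method", METHODS)
    @pytest.mark.parametrize("p, n", [(0.5, 26), (0.9, 45), (0.2, 34)])
    def test_equivalence_quadrature_matches_closed_form(self, method, p, n):
        scn = pt.PowerScenario(mu=0.0, sigma=1.0, p=p, n=n,
                               theta_t=pt.z_quantile(p), delta=0.6)
        quad = pt.power_equivalence_approx_quadrature(method, scn)
        closed = pt.power_approx(method, "equivalence", scn)
        assert quad == pytest.approx(closed, abs=1e-4)

    def test_small_sample_quadrature_vs_simulation(self):
        scn = pt.PowerScenario(mu=0.0, sigma=1.0, p=0.9, n=3,
                               theta_t=pt.z_quantile(0.9), delta=0.6)
        for method in METHODS:
            quad = pt.power_equivalence_approx_quadrature(method, scn)
            sim = pt.simulate_power(method, "equivalence", scn, reps=10**6, seed=17)
            assert abs(quad - sim.reject_rate) <= 3 * max(sim.mc_se, 1e-6)

    def test_exact_method_refused(self):
        scn = pt.PowerScenario(mu=0.0, sigma=1.0, p=0.5, n=10, theta0=0.0)
        with pytest.raises(ValueError):
            pt.power_approx("exact", "difference", scn)
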