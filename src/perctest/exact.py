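"""Exact noncentral-t tests for normal percentiles.

The pivotal result: for an i.i.d. normal sample of size ``n``,
``(xbar - theta) / (s / sqrt(n)) ~ t(nu, -z_p sqrt(n))`` when ``theta`` is
the true ``p``-th percentile.  Critical values are therefore quantiles
``tau_q`` of that noncentral t distribution, and the resulting tests have
size exactly ``alpha`` — the property the central-t approximations lose for
small samples and extreme percentiles.

Three formulations are covered:

* difference  — H0: theta = theta0 vs H1: theta != theta0 (two-sided)
* noninferiority — one-sided in either direction
* equivalence — TOST: H1: |theta - theta_t| < delta; reject when both
  one-sided statistics clear their noncentral-t critical values.
"""

from __future__ import annotations

import math
import warnings

from ._power import power_value, tost_power_quadrature
from .core import SummaryStats, nct_cdf, nct_quantile, z_quantile
from .hypotheses import HypothesisSpec, Method, TestResult, TestType

__all__ = [
    "test_percentile_exact",
    "test_equivalence_exact",
    "power_exact",
    "power_equivalence_exact_quadrature",
]


def _pivot(num: float, sample: SummaryStats) -> float:
    """Studentized statistic num / (s / sqrt(n)), with the sd = 0 convention."""
    se = sample.sd / math.sqrt(sample.n)
    if se == 0:
        warnings.warn("sample SD is 0; test statistic is degenerate", RuntimeWarning)
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    return num / se


def test_percentile_exact(sample: SummaryStats, spec: HypothesisSpec) -> TestResult:
    """Exact difference or noninferiority test of a normal percentile."""
    if spec.test_type is TestType.EQUIVALENCE:
        raise ValueError("use test_equivalence_exact for equivalence hypotheses")
    nu = sample.df
    ncp = -z_quantile(spec.p) * math.sqrt(sample.n)
    stat = _pivot(sample.mean - spec.theta0, sample)
    f = nct_cdf(stat, nu, ncp) if math.isfinite(stat) else (0.0 if stat < 0 else 1.0)

    if spec.test_type is TestType.DIFFERENCE:
        lo = nct_quantile(spec.alpha / 2, nu, ncp)
        hi = nct_quantile(1 - spec.alpha / 2, nu, ncp)
        reject = stat < lo or stat > hi
        crit = (lo, hi)
        p_value = 2 * min(f, 1 - f)
    elif spec.test_type is TestType.NONINFERIORITY_GREATER:
        crit = nct_quantile(1 - spec.alpha, nu, ncp)
        reject = stat > crit
        p_value = 1 - f
    else:
        crit = nct_quantile(spec.alpha, nu, ncp)
        reject = stat < crit
        p_value = f

    return TestResult(
        method=Method.EXACT,
        test_type=spec.test_type,
        statistic=stat,
        critical_value=crit,
        df=nu,
        ncp=ncp,
        reject=bool(reject),
        p_value=min(p_value, 1.0),
    )


def test_equivalence_exact(sample: SummaryStats, spec: HypothesisSpec) -> TestResult:
    """Exact TOST equivalence test of a normal percentile."""
    if spec.test_type is not TestType.EQUIVALENCE:
        raise ValueError("use test_percentile_exact for non-equivalence hypotheses")
    nu = sample.df
    ncp = -z_quantile(spec.p) * math.sqrt(sample.n)
    t_lower = _pivot(sample.mean - spec.theta_t + spec.delta, sample)
    t_upper = _pivot(sample.mean - spec.theta_t - spec.delta, sample)
    crit_lower = nct_quantile(1 - spec.alpha, nu, ncp)
    crit_upper = nct_quantile(spec.alpha, nu, ncp)
    reject = t_lower > crit_lower and t_upper < crit_upper
    f_l = nct_cdf(t_lower, nu, ncp) if math.isfinite(t_lower) else (0.0 if t_lower < 0 else 1.0)
    f_u = nct_cdf(t_upper, nu, ncp) if math.isfinite(t_upper) else (0.0 if t_upper < 0 else 1.0)
    return TestResult(
        method=Method.EXACT,
        test_type=spec.test_type,
        statistic=(t_lower, t_upper),
        critical_value=(crit_lower, crit_upper),
        df=nu,
        ncp=ncp,
        reject=bool(reject),
        p_value=max(1 - f_l, f_u),
    )


def power_exact(test_type: TestType, scenario) -> float:
    """Analytic power of the exact test under a :class:`~perctest.power.PowerScenario`.

    Equivalence uses the noncentral-t TOST approximation (the chi-square
    expectation with the boundary-crossing event dropped, which is
    numerically negligible); see
    :func:`power_equivalence_exact_quadrature` for the full expectation.
    """
    return power_value(
        Method.EXACT,
        test_type,
        scenario.n,
        scenario.p,
        scenario.alpha,
        scenario.mu,
        scenario.sigma,
        theta0=scenario.theta0,
        theta_t=scenario.theta_t,
        delta=scenario.delta,
    )


def power_equivalence_exact_quadrature(scenario, nodes: int = 256) -> float:
    """Exact equivalence power as the chi-square expectation (quadrature form)."""
    return tost_power_quadrature(
        Method.EXACT,
        scenario.n,
        scenario.p,
        scenario.alpha,
        scenario.mu,
        scenario.sigma,
        scenario.theta_t,
        scenario.delta,
        nodes=nodes,
    )
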