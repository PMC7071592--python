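"""Central-t approximations for percentile tests.

Two classical shortcuts avoid noncentral-t quantiles by standardizing a
percentile point estimator and treating the result as central t with
``nu = n - 1`` degrees of freedom:

* Chakraborti–Li: ``T_M = (theta_m - theta) / sqrt(m s^2 / n)`` with the
  minimum variance unbiased estimator ``theta_m`` and variance inflation
  ``m = 1 + n z_p^2 (c^2 - 1)`` (``Var[theta_m] = m sigma^2 / n``).
* Bland–Altman: ``T_B = (theta_b - theta) / sqrt(b s^2 / n)`` with the
  plug-in estimator ``theta_b`` and ``b = 1 + z_p^2 / 2``.

Both collapse to the exact procedure at ``p = 0.5``.  For small ``n`` and
percentiles far from the median the true sampling distribution is skewed,
so the symmetric central-t critical values misallocate tail error — the
failure mode the Monte Carlo engine quantifies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

from ._power import power_value, tost_power_quadrature
from .core import PercentileSpec, SummaryStats, estimate_percentiles, unbias_factor
from .hypotheses import HypothesisSpec, Method, TestResult, TestType

__all__ = [
    "VarianceFactors",
    "variance_factors",
    "test_percentile_approx",
    "test_equivalence_approx",
    "power_approx",
    "power_equivalence_approx_quadrature",
]


@dataclass(frozen=True)
class VarianceFactors:
    """Variance inflation factors of the standardized percentile estimators."""

    m: float  # Chakraborti-Li, for theta_m
    b: float  # Bland-Altman, for theta_b


def variance_factors(n: int, spec: PercentileSpec) -> VarianceFactors:
    """Inflation factors ``m`` and ``b``; both are 1 at the median."""
    z = spec.z
    c = unbias_factor(n)
    return VarianceFactors(m=1.0 + n * z**2 * (c**2 - 1.0), b=1.0 + z**2 / 2.0)


def _estimate_and_scale(method: Method, sample: SummaryStats, p: float):
    """(estimator value, standard-error scale sqrt(f s^2 / n)) for one method."""
    est = estimate_percentiles(sample, PercentileSpec(p))
    fac = variance_factors(sample.n, PercentileSpec(p))
    if method is Method.CHAKRABORTI_LI:
        return est.theta_m, math.sqrt(fac.m * sample.sd**2 / sample.n)
    if method is Method.BLAND_ALTMAN:
        return est.theta_b, math.sqrt(fac.b * sample.sd**2 / sample.n)
    raise ValueError("approximate tests require method chakraborti_li or bland_altman")


def _standardize(num: float, scale: float) -> float:
    if scale == 0:
        warnings.warn("sample SD is 0; test statistic is degenerate", RuntimeWarning)
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    return num / scale


def test_percentile_approx(
    method: Method, sample: SummaryStats, spec: HypothesisSpec
) -> TestResult:
    """Approximate difference or noninferiority test (central-t reference)."""
    method = Method(method)
    if spec.test_type is TestType.EQUIVALENCE:
        raise ValueError("use test_equivalence_approx for equivalence hypotheses")
    nu = sample.df
    theta_hat, scale = _estimate_and_scale(method, sample, spec.p)
    stat = _standardize(theta_hat - spec.theta0, scale)
    f = stats.t.cdf(stat, nu) if math.isfinite(stat) else (0.0 if stat < 0 else 1.0)

    if spec.test_type is TestType.DIFFERENCE:
        hi = float(stats.t.ppf(1 - spec.alpha / 2, nu))
        crit = (-hi, hi)
        reject = abs(stat) > hi
        p_value = 2 * min(f, 1 - f)
    elif spec.test_type is TestType.NONINFERIORITY_GREATER:
        crit = float(stats.t.ppf(1 - spec.alpha, nu))
        reject = stat > crit
        p_value = 1 - f
    else:
        crit = float(stats.t.ppf(spec.alpha, nu))
        reject = stat < crit
        p_value = f

    return TestResult(
        method=method,
        test_type=spec.test_type,
        statistic=stat,
        critical_value=crit,
        df=nu,
        reject=bool(reject),
        p_value=min(p_value, 1.0),
    )


def test_equivalence_approx(
    method: Method, sample: SummaryStats, spec: HypothesisSpec
) -> TestResult:
    """Approximate TOST equivalence test (central-t reference)."""
    method = Method(method)
    if spec.test_type is not TestType.EQUIVALENCE:
        raise ValueError("use test_percentile_approx for non-equivalence hypotheses")
    nu = sample.df
    theta_hat, scale = _estimate_and_scale(method, sample, spec.p)
    t_lower = _standardize(theta_hat - spec.theta_t + spec.delta, scale)
    t_upper = _standardize(theta_hat - spec.theta_t - spec.delta, scale)
    crit_hi = float(stats.t.ppf(1 - spec.alpha, nu))
    reject = t_lower > crit_hi and t_upper < -crit_hi
    f_l = stats.t.cdf(t_lower, nu) if math.isfinite(t_lower) else (0.0 if t_lower < 0 else 1.0)
    f_u = stats.t.cdf(t_upper, nu) if math.isfinite(t_upper) else (0.0 if t_upper < 0 else 1.0)
    return TestResult(
        method=method,
        test_type=spec.test_type,
        statistic=(t_lower, t_upper),
        critical_value=(crit_hi, -crit_hi),
        df=nu,
        reject=bool(reject),
        p_value=max(1 - f_l, f_u),
    )


def power_approx(method: Method, test_type: TestType, scenario) -> float:
    """Analytic power of an approximate test.

    The rejection event is re-expressed on the pivotal-statistic scale
    (whose law is noncentral t), so the power is a noncentral-t tail
    probability of the shifted central-t critical values.
    """
    method = Method(method)
    if method is Method.EXACT:
        raise ValueError("power_approx requires an approximate method")
    return power_value(
        method,
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


def power_equivalence_approx_quadrature(method: Method, scenario, nodes: int = 256) -> float:
    """Approximate-method equivalence power as the chi-square expectation."""
    method = Method(method)
    if method is Method.EXACT:
        raise ValueError("power_equivalence_approx_quadrature requires an approximate method")
    return tost_power_quadrature(
        method,
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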