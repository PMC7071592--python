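"""Shared power machinery for the exact and approximate procedures.

Every test in the package — exact or approximate, one- or two-sided —
rejects based on the pivotal statistic ``T = (xbar - theta0) / (s /
sqrt(n))``, whose sampling law is the noncentral t ``t(nu, Delta)`` with
``Delta = (mu - theta0) * sqrt(n) / sigma``.  The three methods differ only
in where they place the critical value on that pivotal scale:

* exact:           ``tau_q`` — the q-quantile of ``t(nu, -z_p sqrt(n))``
* Chakraborti–Li:  ``t_q sqrt(m) - z_p c sqrt(n)``, ``m = 1 + n z_p^2 (c^2 - 1)``
* Bland–Altman:    ``t_q sqrt(b) - z_p sqrt(n)``,   ``b = 1 + z_p^2 / 2``

(the approximate forms follow algebraically from standardizing the
percentile estimators and moving the estimator offset onto the critical
value).  All analytic power functions are then noncentral-t tail
probabilities of these critical values.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .core import nct_cdf, nct_quantile, nct_sf, z_quantile
from .errors import ComputationError
from .hypotheses import Method, TestType

__all__ = ["pivotal_critical", "power_value", "tost_power_quadrature"]


def _unbias_factor_arr(n):
    nu = np.asarray(n, dtype=float) - 1.0
    return np.sqrt(nu / 2.0) * np.exp(special.gammaln(nu / 2.0) - special.gammaln((nu + 1.0) / 2.0))


def pivotal_critical(method: Method, q, n, p: float):
    """Critical value at quantile level ``q`` on the pivotal-statistic scale.

    Vectorized over ``q`` and ``n``.
    """
    method = Method(method)
    n = np.asarray(n)
    nu = n - 1
    z = z_quantile(p)
    if method is Method.EXACT:
        out = nct_quantile(q, nu, -z * np.sqrt(n))
    elif method is Method.CHAKRABORTI_LI:
        c = _unbias_factor_arr(n)
        m = 1.0 + n * z**2 * (c**2 - 1.0)
        out = stats.t.ppf(q, nu) * np.sqrt(m) - z * c * np.sqrt(n)
    else:  # Bland-Altman
        b = 1.0 + z**2 / 2.0
        out = stats.t.ppf(q, nu) * np.sqrt(b) - z * np.sqrt(n)
    if np.ndim(q) == 0 and np.ndim(n) == 0:
        return float(out)
    return np.asarray(out, dtype=float)


def power_value(
    method: Method,
    test_type: TestType,
    n,
    p: float,
    alpha: float,
    mu: float,
    sigma: float,
    theta0=None,
    theta_t=None,
    delta=None,
):
    """Analytic power (probability of rejection) at the stated truth.

    For equivalence this is the noncentral-t TOST approximation, which
    ignores the numerically negligible event that the two one-sided
    critical bounds cross; the raw difference of tail probabilities is
    clipped at 0.  Vectorized over ``n``.
    """
    method = Method(method)
    test_type = TestType(test_type)
    n_arr = np.asarray(n)
    nu = n_arr - 1
    root_n = np.sqrt(n_arr)

    if test_type is TestType.EQUIVALENCE:
        lo = pivotal_critical(method, alpha, n_arr, p)
        hi = pivotal_critical(method, 1 - alpha, n_arr, p)
        delta_u = (mu - theta_t - delta) * root_n / sigma
        delta_l = (mu - theta_t + delta) * root_n / sigma
        raw = nct_cdf(lo, nu, delta_u) - nct_cdf(hi, nu, delta_l)
        out = np.clip(raw, 0.0, 1.0)
    else:
        ncp = (mu - theta0) * root_n / sigma
        if test_type is TestType.DIFFERENCE:
            lo = pivotal_critical(method, alpha / 2, n_arr, p)
            hi = pivotal_critical(method, 1 - alpha / 2, n_arr, p)
            out = nct_cdf(lo, nu, ncp) + nct_sf(hi, nu, ncp)
        elif test_type is TestType.NONINFERIORITY_GREATER:
            out = nct_sf(pivotal_critical(method, 1 - alpha, n_arr, p), nu, ncp)
        else:
            out = nct_cdf(pivotal_critical(method, alpha, n_arr, p), nu, ncp)

    if np.ndim(n) == 0:
        return float(out)
    return np.asarray(out, dtype=float)


def tost_power_quadrature(
    method: Method,
    n: int,
    p: float,
    alpha: float,
    mu: float,
    sigma: float,
    theta_t: float,
    delta: float,
    nodes: int = 256,
) -> float:
    """Equivalence power as the exact chi-square expectation.

    Integrates ``E_K[ H {Phi(U) - Phi(L)} ]`` over ``K ~ chi2(nu)`` by
    Gauss–Legendre quadrature on ``K < kappa``, where ``kappa`` is the point
    at which the two one-sided acceptance bounds cross (the indicator ``H``
    is zero beyond it).  Convergence is checked by doubling the panel.
    """
    if delta is None or not (delta > 0):
        if delta == 0:
            return 0.0
        raise ValueError(f"equivalence margin delta must be > 0, got {delta}")
    nu = n - 1
    root_n = np.sqrt(n)
    lo = float(pivotal_critical(method, alpha, n, p))
    hi = float(pivotal_critical(method, 1 - alpha, n, p))
    kappa = 4.0 * nu * n * delta**2 / (sigma**2 * (hi - lo) ** 2)
    upper = min(kappa, float(stats.chi2.ppf(1 - 1e-12, nu)))
    if upper <= 0:
        return 0.0

    def integral(k_nodes: int) -> float:
        x, w = np.polynomial.legendre.leggauss(k_nodes)
        k = 0.5 * upper * (x + 1.0)
        w = 0.5 * upper * w
        rk = np.sqrt(k / nu)
        u = (theta_t + delta - mu) * root_n / sigma + lo * rk
        lw = (theta_t - delta - mu) * root_n / sigma + hi * rk
        f = stats.chi2.pdf(k, nu) * (stats.norm.cdf(u) - stats.norm.cdf(lw))
        return float(np.sum(w * f))

    est, refined = integral(nodes), integral(2 * nodes)
    if not np.isfinite(est) or abs(est - refined) > 1e-7:
        raise ComputationError(
            f"equivalence-power quadrature did not converge: {nodes} nodes gave {est}, "
            f"{2 * nodes} nodes gave {refined} (kappa={kappa:.6g}, upper={upper:.6g})"
        )
    return min(max(refined, 0.0), 1.0)
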