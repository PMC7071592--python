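"""Percentile estimators and distribution primitives.

A normal percentile is a linear function of the population mean and
standard deviation, ``theta = mu + z_p * sigma``.  Two point estimators are
in common use: the plug-in estimator ``theta_b = xbar + z_p * s`` (biased,
because ``E[S] < sigma``) and the minimum variance unbiased estimator
``theta_m = xbar + z_p * c * s``, where ``c`` is the gamma-ratio factor that
removes the downward bias of ``S``.

This module also provides the single entry point for the noncentral t
distribution used by every exact procedure: the pivotal quantity
``(xbar - theta) / (s / sqrt(n))`` follows ``t(n - 1, -z_p * sqrt(n))``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "SummaryStats",
    "PercentileSpec",
    "PercentileEstimates",
    "z_quantile",
    "unbias_factor",
    "estimate_percentiles",
    "nct_cdf",
    "nct_sf",
    "nct_quantile",
    "summarize",
]


@dataclass(frozen=True)
class SummaryStats:
    """Sufficient statistics of one i.i.d. normal sample.

    Parameters
    ----------
    n : int
        Sample size, at least 2.
    mean : float
        Sample mean, in the units of the measurements.
    sd : float
        Sample standard deviation with divisor ``n - 1``.
    """

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"sample size must be an integer >= 2, got {self.n}")
        if not math.isfinite(self.mean):
            raise ValueError("sample mean must be finite")
        if not (self.sd >= 0):
            raise ValueError(f"sample SD must be >= 0, got {self.sd}")
        object.__setattr__(self, "n", int(self.n))

    @property
    def df(self) -> int:
        """Degrees of freedom ``n - 1``."""
        return self.n - 1


@dataclass(frozen=True)
class PercentileSpec:
    """Which population percentile is under study.

    ``p`` is the probability level: ``p = 0.9`` means the 90th percentile.
    """

    p: float

    def __post_init__(self) -> None:
        if not (0 < self.p < 1):
            raise ValueError(f"percentile level must lie in (0, 1), got {self.p}")

    @property
    def z(self) -> float:
        """Standard-normal quantile ``z_p``."""
        return z_quantile(self.p)


@dataclass(frozen=True)
class PercentileEstimates:
    """Point estimates of a normal percentile from one sample."""

    theta_b: float  # plug-in (biased) estimate
    theta_m: float  # minimum variance unbiased estimate


def z_quantile(p: float) -> float:
    """Standard normal quantile at probability ``p`` (0 < p < 1)."""
    if not (0 < p < 1):
        raise ValueError(f"probability must lie in (0, 1), got {p}")
    return float(stats.norm.ppf(p))


def unbias_factor(n: int) -> float:
    """Unbiasing factor ``c = sqrt(nu/2) * Gamma(nu/2) / Gamma((nu+1)/2)``.

    Satisfies ``E[c * S] = sigma`` for a normal sample of size ``n``
    (``nu = n - 1``).  Evaluated through log-gamma differences so it is
    stable for large ``nu``; ``c > 1`` always, with ``c -> 1`` as
    ``n -> infinity``.
    """
    if int(n) != n or n < 2:
        raise ValueError(f"sample size must be an integer >= 2, got {n}")
    nu = n - 1
    return float(
        math.sqrt(nu / 2.0) * math.exp(special.gammaln(nu / 2.0) - special.gammaln((nu + 1) / 2.0))
    )


def estimate_percentiles(sample: SummaryStats, spec: PercentileSpec) -> PercentileEstimates:
    """Biased and minimum variance unbiased estimates of the ``p``-th percentile."""
    z = spec.z
    c = unbias_factor(sample.n)
    return PercentileEstimates(
        theta_b=sample.mean + z * sample.sd,
        theta_m=sample.mean + z * c * sample.sd,
    )


def summarize(values) -> SummaryStats:
    """Reduce raw measurements to :class:`SummaryStats` (SD divisor ``n - 1``)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError(f"need at least 2 finite values, got {x.size}")
    return SummaryStats(n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def _validate_nct(df, ncp) -> None:
    if np.any(np.asarray(df) < 1):
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    if not np.all(np.isfinite(ncp)):
        raise ValueError(f"noncentrality must be finite, got {ncp}")


def _nct_cdf_fallback(x, df, ncp):
    """Jennett-Welch normal approximation of the noncentral-t CDF.

    Used only where the library evaluator underflows to NaN, which happens
    deep in the tails (true probabilities below ~1e-35 or within 1e-16 of
    1), where the approximation's absolute error is negligible.
    """
    x = np.asarray(x, dtype=float)
    df = np.asarray(df, dtype=float)
    unbias = 1.0 - 3.0 / (4.0 * df - 1.0)  # E[S/sigma] to second order
    z = (x * unbias - ncp) / np.sqrt(1.0 + x * x * (1.0 - unbias * unbias))
    return stats.norm.cdf(z)


def _patch_nan(raw, x, df, ncp, upper: bool):
    bad = ~np.isfinite(raw)
    if not np.any(bad):
        return raw
    fb = _nct_cdf_fallback(x, df, ncp)
    if upper:
        fb = 1.0 - fb
    return np.where(bad, fb, raw)


def nct_cdf(x, df, ncp):
    """CDF of the noncentral t distribution ``t(df, ncp)``.

    Thin wrapper around :func:`scipy.stats.nct` so the whole package shares
    one evaluator.  Falls back to the central t when ``ncp`` is exactly 0,
    and to a normal approximation where the library result underflows to
    NaN in the far tails.
    """
    _validate_nct(df, ncp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        raw = np.where(
            np.asarray(ncp) == 0,
            stats.t.cdf(x, df),
            stats.nct.cdf(x, df, np.where(np.asarray(ncp) == 0, 1.0, ncp)),
        )
        out = _patch_nan(raw, x, df, ncp, upper=False)
    if np.ndim(x) == 0 and np.ndim(ncp) == 0 and np.ndim(df) == 0:
        return float(out)
    return out


def nct_sf(x, df, ncp):
    """Survival function ``P{t(df, ncp) > x}``."""
    _validate_nct(df, ncp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        raw = np.where(
            np.asarray(ncp) == 0,
            stats.t.sf(x, df),
            stats.nct.sf(x, df, np.where(np.asarray(ncp) == 0, 1.0, ncp)),
        )
        out = _patch_nan(raw, x, df, ncp, upper=True)
    if np.ndim(x) == 0 and np.ndim(ncp) == 0 and np.ndim(df) == 0:
        return float(out)
    return out


def nct_quantile(q, df, ncp):
    """Quantile ``tau_q`` of the noncentral t distribution ``t(df, ncp)``."""
    qa = np.asarray(q, dtype=float)
    if np.any((qa <= 0) | (qa >= 1)):
        raise ValueError(f"quantile level must lie in (0, 1), got {q}")
    _validate_nct(df, ncp)
    if np.ndim(q) == 0 and np.ndim(ncp) == 0 and np.ndim(df) == 0:
        if ncp == 0:
            return float(stats.t.ppf(q, df))
        return float(stats.nct.ppf(q, df, ncp))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.where(
            np.asarray(ncp) == 0, stats.t.ppf(q, df), stats.nct.ppf(q, df, np.where(ncp == 0, 1.0, ncp))
        )
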