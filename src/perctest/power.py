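"""Power evaluation and minimal sample-size determination.

A :class:`PowerScenario` holds the population truth (``mu``, ``sigma``),
the design (``n``, percentile level ``p``, ``alpha``) and the hypothesis
thresholds.  Power enters through the noncentrality arguments

``Delta   = (mu - theta0)  sqrt(n) / sigma``  (difference / noninferiority)
``Delta_L = (mu - theta_t + delta) sqrt(n) / sigma``  and
``Delta_U = (mu - theta_t - delta) sqrt(n) / sigma``  (equivalence TOST).

Sample sizes are found by an upward scan over ``n`` (evaluated in
vectorized blocks), which guarantees minimality even where the power is
not perfectly monotone at tiny ``n`` for extreme percentiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._power import power_value
from .core import z_quantile
from .errors import ComputationError
from .hypotheses import Method, TestType

__all__ = [
    "PowerScenario",
    "SampleSizeResult",
    "power",
    "required_sample_size",
    "power_curve",
]


@dataclass(frozen=True)
class PowerScenario:
    """Population truth and design for power / sample-size analysis."""

    mu: float
    sigma: float
    p: float
    alpha: float = 0.05
    n: Optional[int] = None
    theta0: Optional[float] = None
    theta_t: Optional[float] = None
    delta: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (0 < self.p < 1):
            raise ValueError(f"percentile level must lie in (0, 1), got {self.p}")
        if not (0 < self.alpha < 0.5):
            raise ValueError(f"alpha must lie in (0, 0.5), got {self.alpha}")
        if self.n is not None and (int(self.n) != self.n or self.n < 2):
            raise ValueError(f"design sample size must be an integer >= 2, got {self.n}")
        if self.delta is not None and not (self.delta > 0):
            raise ValueError(f"delta must be > 0, got {self.delta}")

    @property
    def theta(self) -> float:
        """True percentile ``mu + z_p sigma``."""
        return self.mu + z_quantile(self.p) * self.sigma

    def _require_n(self) -> int:
        if self.n is None:
            raise ValueError("scenario has no design sample size n")
        return self.n

    @property
    def ncp(self) -> float:
        """Noncentrality ``Delta`` of the pivotal statistic under the truth."""
        n = self._require_n()
        return (self.mu - self.theta0) * math.sqrt(n) / self.sigma

    @property
    def ncp_lower(self) -> float:
        n = self._require_n()
        return (self.mu - self.theta_t + self.delta) * math.sqrt(n) / self.sigma

    @property
    def ncp_upper(self) -> float:
        n = self._require_n()
        return (self.mu - self.theta_t - self.delta) * math.sqrt(n) / self.sigma


@dataclass(frozen=True)
class SampleSizeResult:
    """Minimal sample size achieving a target power."""

    n_required: int
    achieved_power: float
    target_power: float
    power_curve: Optional[Tuple[Tuple[int, float], ...]] = None


def power(method: Method, test_type: TestType, scenario: PowerScenario) -> float:
    """Analytic power of the chosen method and test type at ``scenario.n``."""
    scenario._require_n()
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


def _power_at(method, test_type, scenario: PowerScenario, n_values) -> np.ndarray:
    return np.atleast_1d(
        power_value(
            method,
            test_type,
            np.asarray(n_values),
            scenario.p,
            scenario.alpha,
            scenario.mu,
            scenario.sigma,
            theta0=scenario.theta0,
            theta_t=scenario.theta_t,
            delta=scenario.delta,
        )
    )


def required_sample_size(
    method: Method,
    test_type: TestType,
    scenario: PowerScenario,
    target_power: float = 0.80,
    n_max: int = 10**6,
    keep_curve: bool = False,
) -> SampleSizeResult:
    """Smallest ``n`` whose analytic power reaches ``target_power``.

    Scans ``n = 2, 3, ...`` upward (in vectorized blocks) and returns the
    first hit, so the result is minimal even if power dips locally.
    """
    if not (0 < target_power < 1):
        raise ValueError(f"target power must lie in (0, 1), got {target_power}")
    if scenario.alpha >= target_power:
        raise ValueError("target power must exceed the significance level")
    curve: List[Tuple[int, float]] = []
    start, block = 2, 64
    while start <= n_max:
        stop = min(start + block, n_max + 1)
        ns = np.arange(start, stop)
        pw = _power_at(method, test_type, scenario, ns)
        if keep_curve:
            curve.extend(zip(ns.tolist(), pw.tolist()))
        hits = np.nonzero(pw >= target_power)[0]
        if hits.size:
            i = int(hits[0])
            return SampleSizeResult(
                n_required=int(ns[i]),
                achieved_power=float(pw[i]),
                target_power=target_power,
                power_curve=tuple(curve) if keep_curve else None,
            )
        start = stop
        block = min(block * 2, 8192)
    raise ComputationError(
        f"no sample size up to {n_max} reaches power {target_power} "
        f"(power at cap: {float(_power_at(method, test_type, scenario, [n_max])[0]):.6f})"
    )


def power_curve(
    method: Method,
    test_type: TestType,
    scenario: PowerScenario,
    n_range: Sequence[int],
) -> List[Tuple[int, float]]:
    """Analytic power evaluated at each sample size in ``n_range``."""
    ns = [int(n) for n in n_range]
    if not ns:
        raise ValueError("n_range must be nonempty")
    if min(ns) < 2:
        raise ValueError("every sample size must be >= 2")
    pw = _power_at(method, test_type, scenario, np.asarray(ns))
    return list(zip(ns, pw.tolist()))


def scenario_with_n(scenario: PowerScenario, n: int) -> PowerScenario:
    """Copy of ``scenario`` with the design sample size replaced."""
    return replace(scenario, n=n)
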