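"""Hypothesis specifications and test results shared by all procedures."""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Tuple, Union


class Method(str, enum.Enum):
    """Which sampling distribution backs the test.

    ``exact`` uses the noncentral t law of the pivotal statistic;
    ``chakraborti_li`` and ``bland_altman`` use central-t approximations for
    the standardized unbiased and plug-in percentile estimators respectively.
    """

    EXACT = "exact"
    CHAKRABORTI_LI = "chakraborti_li"
    BLAND_ALTMAN = "bland_altman"


class TestType(str, enum.Enum):
    DIFFERENCE = "difference"
    NONINFERIORITY_GREATER = "noninferiority_greater"  # H1: theta > theta0
    NONINFERIORITY_LESS = "noninferiority_less"        # H1: theta < theta0
    EQUIVALENCE = "equivalence"                        # H1: |theta - theta_t| < delta


@dataclass(frozen=True)
class HypothesisSpec:
    """A percentile hypothesis: test type, thresholds, level and percentile.

    Exactly one of ``theta0`` (difference / noninferiority) or
    ``theta_t`` + ``delta`` (equivalence) must be given.
    """

    test_type: TestType
    p: float
    alpha: float = 0.05
    theta0: Optional[float] = None
    theta_t: Optional[float] = None
    delta: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "test_type", TestType(self.test_type))
        if not (0 < self.p < 1):
            raise ValueError(f"percentile level must lie in (0, 1), got {self.p}")
        if not (0 < self.alpha < 0.5):
            raise ValueError(f"alpha must lie in (0, 0.5), got {self.alpha}")
        if self.test_type is TestType.EQUIVALENCE:
            if self.theta0 is not None:
                raise ValueError("equivalence tests take theta_t and delta, not theta0")
            if self.theta_t is None or self.delta is None:
                raise ValueError("equivalence tests require theta_t and delta")
            if not (self.delta > 0):
                raise ValueError(f"equivalence margin delta must be > 0, got {self.delta}")
        else:
            if self.theta0 is None:
                raise ValueError(f"{self.test_type.value} tests require theta0")
            if self.theta_t is not None or self.delta is not None:
                raise ValueError("theta_t/delta apply to equivalence tests only")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one percentile test.

    ``statistic`` and ``critical_value`` are scalars for difference and
    noninferiority tests, and ``(lower, upper)`` pairs for equivalence
    (TOST) tests, whose rejection rule is ``lower_stat > lower_crit and
    upper_stat < upper_crit``.  ``ncp`` is the noncentrality of the reference
    distribution for the exact method and ``None`` for the central-t
    approximations.  ``p_value`` is a convenience extension: the reference
    distributions are asymmetric, so the two-sided value is the conventional
    ``2 * min(F, 1 - F)``.
    """

    method: Method
    test_type: TestType
    statistic: Union[float, Tuple[float, float]]
    critical_value: Union[float, Tuple[float, float]]
    df: int
    reject: bool
    ncp: Optional[float] = None
    p_value: Optional[float] = None
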