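"""Monte Carlo verification engine.

Reproduces the simulation design used to compare the exact and approximate
procedures: draw many samples from a null (or alternative) normal
population, apply a test to each, and tally tail-wise rejection rates.
Under the null the excess of each rate over its nominal value measures the
Type I error distortion of the method; under an alternative the overall
rate estimates the analytic power.

All replicate samples in one call are drawn as a single block from one
seeded generator, and each table cell gets its own child seed spawned from
the root seed, so per-cell results do not depend on evaluation order.
Every replicate is reduced to (mean, sd with divisor ``n - 1``) and tested
through the same rejection rules as user data, expressed on the pivotal
scale of ``(xbar - theta0) / (s / sqrt(n))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._power import pivotal_critical
from .core import z_quantile
from .hypotheses import Method, TestType
from .power import PowerScenario, required_sample_size

__all__ = [
    "NullConfig",
    "SimulationResult",
    "simulate_error_rates",
    "simulate_power",
    "regenerate_table",
]

_TABLE_MUS = {1: (0.4, 0.6), 2: (0.4, 0.6), 3: (0.0, 0.3)}
_TABLE_TEST = {
    1: TestType.DIFFERENCE,
    2: TestType.NONINFERIORITY_GREATER,
    3: TestType.EQUIVALENCE,
}
_TABLE_PS = tuple(round(0.1 * i, 1) for i in range(1, 10))
_EQ_DELTA = 0.6  # equivalence margin of the table-3 study


@dataclass(frozen=True)
class NullConfig:
    """Null population for a Type I error study.

    For difference/noninferiority the null percentile is
    ``theta0 = mu0 + z_p sigma0``.  For equivalence, supply ``theta_t`` and
    ``delta``; samples are drawn with the true percentile sitting exactly on
    the boundary ``theta = theta_t - delta`` (i.e. ``mu = theta_t - delta -
    z_p sigma0``).
    """

    mu0: float = 0.0
    sigma0: float = 1.0
    theta_t: Optional[float] = None
    delta: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.sigma0 > 0):
            raise ValueError(f"sigma0 must be > 0, got {self.sigma0}")
        if self.delta is not None and not (self.delta > 0):
            raise ValueError(f"delta must be > 0, got {self.delta}")


@dataclass(frozen=True)
class SimulationResult:
    """Rejection rates from one simulation cell.

    ``reject_rate`` is the overall rejection proportion; for two-sided
    tests it is the sum of ``lower_rate`` and ``upper_rate``.  ``error``
    fields are rate minus nominal (``alpha`` overall, ``alpha/2`` per tail
    of a two-sided test) and are ``None`` for power simulations, where no
    nominal rate applies.  ``mc_se`` is the binomial standard error
    ``sqrt(r (1 - r) / reps)`` of the matching rate.
    """

    reps: int
    seed: Optional[int]
    reject_rate: float
    mc_se: float
    lower_rate: Optional[float] = None
    upper_rate: Optional[float] = None
    error: Optional[float] = None
    lower_error: Optional[float] = None
    upper_error: Optional[float] = None
    mc_se_lower: Optional[float] = None
    mc_se_upper: Optional[float] = None


def _binom_se(rate: float, reps: int) -> float:
    return math.sqrt(rate * (1.0 - rate) / reps)


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _seed_label(seed) -> Optional[int]:
    return seed if isinstance(seed, (int, np.integer)) else None


def _simulate_cell(
    method: Method,
    test_type: TestType,
    data_mu: float,
    data_sigma: float,
    n: int,
    p: float,
    alpha: float,
    theta0: Optional[float],
    theta_t: Optional[float],
    delta: Optional[float],
    reps: int,
    rng: np.random.Generator,
):
    """Tail-wise rejection masks for `reps` samples of size `n`."""
    x = rng.normal(data_mu, data_sigma, size=(reps, n))
    means = x.mean(axis=1)
    sds = x.std(axis=1, ddof=1)
    se = sds / math.sqrt(n)

    if test_type is TestType.EQUIVALENCE:
        lo_crit = float(pivotal_critical(method, 1 - alpha, n, p))
        up_crit = float(pivotal_critical(method, alpha, n, p))
        t_lower = (means - theta_t + delta) / se
        t_upper = (means - theta_t - delta) / se
        reject = (t_lower > lo_crit) & (t_upper < up_crit)
        return reject, None, None
    t = (means - theta0) / se
    if test_type is TestType.DIFFERENCE:
        lower = t < float(pivotal_critical(method, alpha / 2, n, p))
        upper = t > float(pivotal_critical(method, 1 - alpha / 2, n, p))
        return lower | upper, lower, upper
    if test_type is TestType.NONINFERIORITY_GREATER:
        return t > float(pivotal_critical(method, 1 - alpha, n, p)), None, None
    return t < float(pivotal_critical(method, alpha, n, p)), None, None


def simulate_error_rates(
    method: Method,
    test_type: TestType,
    null_config: NullConfig,
    n: int,
    p: float,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed=None,
) -> SimulationResult:
    """Simulated Type I error rates at the null boundary.

    Draws ``reps`` samples of size ``n`` from the null population, applies
    the specified test, and reports rejection rates minus their nominal
    values (``alpha/2`` per tail and ``alpha`` overall for two-sided tests;
    ``alpha`` for one-sided and equivalence tests).
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    method, test_type = Method(method), TestType(test_type)
    z = z_quantile(p)
    if test_type is TestType.EQUIVALENCE:
        if null_config.theta_t is None or null_config.delta is None:
            raise ValueError("equivalence null requires theta_t and delta in NullConfig")
        theta0 = None
        theta_t, delta = null_config.theta_t, null_config.delta
        data_mu = theta_t - delta - z * null_config.sigma0
    else:
        theta0 = null_config.mu0 + z * null_config.sigma0
        theta_t = delta = None
        data_mu = null_config.mu0

    reject, lower, upper = _simulate_cell(
        method, test_type, data_mu, null_config.sigma0, n, p, alpha,
        theta0, theta_t, delta, reps, _as_rng(seed),
    )
    rate = float(reject.mean())
    res = dict(
        reps=reps,
        seed=_seed_label(seed),
        reject_rate=rate,
        mc_se=_binom_se(rate, reps),
        error=rate - alpha,
    )
    if lower is not None:
        lo, up = float(lower.mean()), float(upper.mean())
        res.update(
            lower_rate=lo,
            upper_rate=up,
            lower_error=lo - alpha / 2,
            upper_error=up - alpha / 2,
            mc_se_lower=_binom_se(lo, reps),
            mc_se_upper=_binom_se(up, reps),
        )
    return SimulationResult(**res)


def simulate_power(
    method: Method,
    test_type: TestType,
    scenario: PowerScenario,
    reps: int = 10_000,
    seed=None,
) -> SimulationResult:
    """Simulated power: rejection proportion under the alternative of ``scenario``."""
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    method, test_type = Method(method), TestType(test_type)
    if scenario.n is None:
        raise ValueError("scenario has no design sample size n")
    reject, lower, upper = _simulate_cell(
        method, test_type, scenario.mu, scenario.sigma, scenario.n, scenario.p,
        scenario.alpha, scenario.theta0, scenario.theta_t, scenario.delta,
        reps, _as_rng(seed),
    )
    rate = float(reject.mean())
    return SimulationResult(
        reps=reps,
        seed=_seed_label(seed),
        reject_rate=rate,
        mc_se=_binom_se(rate, reps),
        lower_rate=float(lower.mean()) if lower is not None else None,
        upper_rate=float(upper.mean()) if upper is not None else None,
    )


def _table_scenario(table_id: int, mu: float, p: float, alpha: float) -> PowerScenario:
    z = z_quantile(p)
    if table_id == 3:
        return PowerScenario(mu=mu, sigma=1.0, p=p, alpha=alpha, theta_t=z, delta=_EQ_DELTA)
    return PowerScenario(mu=mu, sigma=1.0, p=p, alpha=alpha, theta0=z)


def regenerate_table(
    table_id: int,
    methods: Optional[Iterable[Method]] = None,
    reps: int = 10_000,
    seed=None,
    alpha: float = 0.05,
    target_power: float = 0.80,
    ps: Sequence[float] = _TABLE_PS,
    include_simulation: bool = True,
) -> pd.DataFrame:
    """Regenerate one of the three benchmark tables.

    Table 1 covers the two-sided difference test, table 2 the one-sided
    noninferiority test, table 3 the TOST equivalence test (margin 0.6,
    target ``theta_t = z_p``).  For each population mean and percentile
    level the analytic sample size reaching ``target_power`` is computed
    per method, and (optionally) the Type I error excess at that sample
    size is simulated at the null boundary.
    """
    if table_id not in (1, 2, 3):
        raise ValueError(f"table_id must be 1, 2 or 3, got {table_id}")
    methods = [Method(m) for m in (methods or list(Method))]
    test_type = _TABLE_TEST[table_id]
    cells = [(mu, p) for mu in _TABLE_MUS[table_id] for p in ps]
    children = np.random.SeedSequence(seed).spawn(len(cells) * len(methods))

    rows = []
    k = 0
    for mu, p in cells:
        row = {"mu": mu, "p": p}
        for method in methods:
            scn = _table_scenario(table_id, mu, p, alpha)
            n_req = required_sample_size(method, test_type, scn, target_power).n_required
            row[f"{method.value}_N"] = n_req
            if include_simulation and reps > 0:
                if table_id == 3:
                    null = NullConfig(sigma0=1.0, theta_t=z_quantile(p), delta=_EQ_DELTA)
                else:
                    null = NullConfig(mu0=0.0, sigma0=1.0)
                sim = simulate_error_rates(
                    method, test_type, null, n_req, p, alpha, reps,
                    np.random.default_rng(children[k]),
                )
                if test_type is TestType.DIFFERENCE:
                    row[f"{method.value}_lower_error"] = sim.lower_error
                    row[f"{method.value}_upper_error"] = sim.upper_error
                    row[f"{method.value}_two_tail_error"] = sim.error
                else:
                    row[f"{method.value}_error"] = sim.error
            k += 1
        rows.append(row)
    return pd.DataFrame(rows)
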