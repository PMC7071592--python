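import pytest
from hypothesis import settings

import perctest as pt

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def dissolution():
    """Summary statistics of the drug-dissolution quality-control sample."""
    return pt.SummaryStats(n=15, mean=50.10, sd=1.31)


@pytest.fixture
def diff_spec():
    return pt.HypothesisSpec("difference", p=0.9, theta0=50.8379, alpha=0.05)


@pytest.fixture
def eq_spec():
    return pt.HypothesisSpec("equivalence", p=0.9, theta_t=51.6660, delta=1.2, alpha=0.05)
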