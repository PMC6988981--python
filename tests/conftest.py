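import pytest
from hypothesis import HealthCheck, settings

from penbayes import BaselineRisk, CaseControlCounts

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def example_counts() -> CaseControlCounts:
    """The worked single-variant example: 10 carriers in 1000 cases, 5 in 1000 controls."""
    return CaseControlCounts(
        carriers_cases=10, total_cases=1000, carriers_controls=5, total_controls=1000
    )


@pytest.fixture
def one_percent_baseline() -> BaselineRisk:
    return BaselineRisk(0.01)
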