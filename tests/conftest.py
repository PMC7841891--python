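import pytest
from hypothesis import settings

from afib_cea import StrategyOutcome, base_case_inputs, reference_results

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


@pytest.fixture
def base_inputs():
    """A fresh mutable copy of the shipped base-case parameter set."""
    return base_case_inputs()


@pytest.fixture(scope="session")
def published_outcomes():
    """Published base-case totals wrapped as StrategyOutcome objects."""
    return [
        StrategyOutcome(strategy=s, total_cost=c, total_qaly=q, life_years=q)
        for s, (c, q) in reference_results().items()
    ]
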