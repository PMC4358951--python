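import pytest
from hypothesis import HealthCheck, settings

import rhdcea

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Default (published base-case) parameter set, shared read-only."""
    return rhdcea.default_parameters()


@pytest.fixture(scope="session")
def base_ledgers(params):
    """Deterministic base-case ledgers for both arms."""
    return {
        arm: rhdcea.run_cohort(params, arm)
        for arm in ("control", "intervention")
    }
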