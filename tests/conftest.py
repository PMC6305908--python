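import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    from emprs.panel import load_reference_panel

    return load_reference_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-subject cohort with default study conditions, shared across
    tests that only read it."""
    from emprs.synthetic import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(n_subjects=120, seed=11))
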