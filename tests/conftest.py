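import pytest
from hypothesis import HealthCheck, settings

from erbt_lc import default_cohort, simulate_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def step_cohort():
    """Study-design cohort (2 groups x 4 operators x 30) with step-shaped
    mean curves, noisy times; change points at 16 (junior) / 13 (senior)."""
    return simulate_cohort(default_cohort(shape="step"), seed=42)


@pytest.fixture(scope="session")
def noiseless_step_cohort():
    """Same design with zero noise: times are exactly two-valued per
    operator with the jump after the configured change point."""
    return simulate_cohort(
        default_cohort(shape="step", time_noise_sd=0.0), seed=7
    )
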