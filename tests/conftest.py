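import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from colitistats import StandardCurve, default_design, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def unit_curve() -> StandardCurve:
    """Curve with slope 0.01 abs/min per mU and zero intercept."""
    return StandardCurve(slope=0.01, intercept=0.0)


@pytest.fixture(scope="session")
def default_cohort_frame():
    """One default 5-arm synthetic cohort (n=8/group), as a frame."""
    from colitistats import cohort_to_frame

    design = default_design(n_per_group=8)
    return cohort_to_frame(generate_cohort(design, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
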