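import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from burrowmap import TypedPointPattern, Window

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_window():
    return Window(0.0, 100.0, 0.0, 100.0)


@pytest.fixture
def csr_pattern(unit_window):
    """50 uniform points of two types in a 100 x 100 m window."""
    rng = np.random.default_rng(7)
    n = 50
    return TypedPointPattern(
        unit_window,
        rng.uniform(0, 100, n),
        rng.uniform(0, 100, n),
        np.array(["K"] * 20 + ["A"] * 30, dtype=object),
    )
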