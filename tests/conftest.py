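import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sicmorph as sm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hemisphere():
    """Discretized hemisphere, r = 500 nm at 5 nm pitch, with its mask."""
    t = sm.make_cap(220, 220, 5.0, 500.0, 500.0)
    mask = sm.segment_object(t, rel_threshold=0.01, min_pixels=16)
    return t, mask


@pytest.fixture(scope="session")
def default_study():
    """One default-preset synthetic study (30 records)."""
    return sm.simulate_study(n_records=30, master_seed=7)


def flat_topography(values, pitch=10.0, direction="forward"):
    return sm.Topography(np.asarray(values, dtype=float), pitch, pitch, direction=direction)
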