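import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_profile():
    """A compact, fast generator profile for pipeline tests."""
    from nmjmorph.synthgen import MuscleProfile

    return MuscleProfile(
        name="TST",
        size_scale=0.8,
        branch_count_range=(8, 14),
        cluster_count_range=(2, 5),
        canvas=256,
    )
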