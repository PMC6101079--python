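import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from permfdr import (  # noqa: E402
    NullDistribution,
    ProteinScore,
    SampleScores,
    build_null,
)


@pytest.fixture
def toy_null() -> NullDistribution:
    """Four decoy scores binned at width 0.25: counts [2, 0, 1, 1]."""
    return build_null([0.1, 0.2, 0.6, 0.9], bin_width=0.25)


@pytest.fixture
def small_sample() -> SampleScores:
    return SampleScores(
        sample_id="s1",
        entries=[
            ProteinScore("A", 0.95),
            ProteinScore("B", 0.30),
            ProteinScore("C", 0.05),
            ProteinScore("DECOY_A", 0.10, decoy=True),
        ],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
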