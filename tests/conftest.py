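import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20_190_620)


@pytest.fixture
def small_tiling():
    from cnvseq.tiling import build_tiling

    return build_tiling([("chr1", 1_000_000), ("chr2", 250_000)], 10_000)
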