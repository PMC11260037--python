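import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "matesim",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("matesim")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map(rng):
    from matesim import build_genome_map

    return build_genome_map(n_markers=40, n_qtl=8, length_cM=100.0, rng=rng)
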