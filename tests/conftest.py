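import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_records():
    """Three hand-built consistent gene records."""
    from ksforge.seqio import GeneRecord

    return [
        GeneRecord("g1", "ATGGCTGCA", "MAA"),
        GeneRecord("g2", "ATGGCAGCC", "MAA"),
        GeneRecord("g3", "ATGTTTAAA", "MFK"),
    ]
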