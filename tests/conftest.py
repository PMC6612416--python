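import matplotlib
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def three_blob_spec():
    """The clean three-blob fixture: well-separated cells, low noise."""
    from coloc import SyntheticSpec

    return SyntheticSpec(seed=42)


@pytest.fixture
def three_blob_pair(three_blob_spec):
    from coloc import generate_pair

    return generate_pair(three_blob_spec)
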