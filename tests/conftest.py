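import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repo",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repo")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_bins():
    """Three-chromosome toy genome: 2.5 Mb / 2 Mb / 1.5 Mb at 1 Mb bins."""
    from karyostab import make_bins

    return make_bins({"chr1": 2_500_000, "chr2": 2_000_000, "chrX": 1_500_000})
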