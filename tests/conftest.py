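import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mcakit.detect import SegmentCall
from mcakit.taxonomy import RegionLists

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lists() -> RegionLists:
    return RegionLists.default()


@pytest.fixture
def make_call():
    def _make(chrom, start, end, etype, cf=0.3, **kw):
        defaults = dict(
            dbaf=0.1, mean_lrr=0.0, cell_fraction=cf, n_hets=100, quality=10.0
        )
        defaults.update(kw)
        return SegmentCall(chrom=chrom, start=start, end=end, type=etype, **defaults)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
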