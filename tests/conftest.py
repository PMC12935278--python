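import numpy as np
import pytest

from octvib.phantom import PhantomSpec
from octvib.reconstruction import AcquisitionSchedule


@pytest.fixture
def schedule() -> AcquisitionSchedule:
    return AcquisitionSchedule()


@pytest.fixture
def coarse_spec() -> PhantomSpec:
    """Phantom at 50 um pitch: fast rendering for unit tests."""
    return PhantomSpec(spacing=0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
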