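import numpy as np
import pytest

from bcgmixer.preprocessing import Segment


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def noise_segment(rng):
    return Segment(samples=rng.normal(size=3000), subject_id="S1", segment_index=0,
                   label="HPT", fs=100.0)
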