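import numpy as np
import pytest

from ethodyn import BehavioralSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_seq(labels, window_seconds=1.0, breaks=(), alphabet=None):
    return BehavioralSequence("test", window_seconds,
                              np.array(list(labels), dtype=object),
                              alphabet=alphabet or (), segment_breaks=breaks)


@pytest.fixture
def simple_seq():
    return make_seq("AAABBA")
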