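import numpy as np
import pytest

from mpbnssfp.sequence import build_optimized_block, build_pulse_train


@pytest.fixture(scope="session")
def train12():
    """The reference 3D pulse train: 12 blocks of 4 pulses at TRp 30 ms."""
    return build_pulse_train(build_optimized_block(30.0), 12, 3000.0)


@pytest.fixture(scope="session")
def train2():
    """Short 2-block train (8 contrasts) for fast reconstruction tests."""
    return build_pulse_train(build_optimized_block(30.0), 2, 3000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
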