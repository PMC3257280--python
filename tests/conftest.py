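import numpy as np
import pytest

from redunet import DecoderDistribution, sample_decoder


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_decoder():
    """Factory for homogeneous (unit-amplitude, uniform-direction) decoders."""

    def make(n_neurons=100, seed=0):
        return sample_decoder(DecoderDistribution.uniform(), n_neurons, seed)

    return make
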