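import numpy as np
import pytest

from replixi.genome import make_genome


@pytest.fixture
def small_genome():
    """One autosome + one X, 10 bins each at 400 kb."""
    return make_genome([("chr1", 4_000_000), ("chrX", 4_000_000)], 400_000)


@pytest.fixture
def autosome_genome():
    """Single 40-bin autosome at 100 kb."""
    return make_genome([("chr1", 4_000_000)], 100_000)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
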