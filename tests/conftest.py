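import numpy as np
import pytest

from rnt1kit import core_io, motif, synthetic


@pytest.fixture(scope="session")
def substrates():
    """The packaged synthetic stand-in substrate table."""
    return motif.default_substrates()


@pytest.fixture(scope="session")
def default_model():
    return motif.default_model()


@pytest.fixture(scope="session")
def small_genome():
    genome, manifest = synthetic.gen_genome(30_000, seed=42)
    return genome, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def interval():
    return core_io.GenomicInterval("chrI", 10, 20, "+")
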