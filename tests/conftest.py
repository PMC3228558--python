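import numpy as np
import pytest

from numtspipe import SequenceRecord, random_sequence


@pytest.fixture(scope="session")
def mito() -> SequenceRecord:
    """Synthetic stand-in for a 16569-bp circular mitochondrial reference."""
    return SequenceRecord("chrM", random_sequence(16569, np.random.default_rng(20110517)))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
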