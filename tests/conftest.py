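import numpy as np
import pytest

from loopgrow.fixtures import make_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Shared fitted corpus: 40 fixtures, fixed seed (the study conditions)."""
    return make_corpus(n_structures=40, seed=11, n_decoys=3)


@pytest.fixture(scope="session")
def bundle(small_corpus):
    return small_corpus.bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
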