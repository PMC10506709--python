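import numpy as np
import pytest

from hotspot1d.embedders import OneHotEmbedder
from hotspot1d.synthetic import SyntheticProteinSpec, generate_proteins


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small motif-planted corpus shared by read-only tests."""
    return generate_proteins(
        SyntheticProteinSpec(n_proteins=12, length_range=(60, 80), imbalance_ratio=10, seed=11)
    )


@pytest.fixture
def one_hot():
    return OneHotEmbedder()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
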