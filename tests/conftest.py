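import numpy as np
import pytest

from phyloconcord.io_core import parse_newick


@pytest.fixture
def quartet_ref():
    """Reference 4-taxon tree AB|CD."""
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
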