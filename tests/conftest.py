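import numpy as np
import pytest

from spacerphy import CRISPRArray


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def homologous_arrays():
    """A small set of related arrays with a conserved trailer core."""
    return [
        CRISPRArray("A", ("n1", "n2", "c1", "c2", "c3")),
        CRISPRArray("B", ("n3", "c1", "c2", "c3")),
        CRISPRArray("C", ("c1", "c2", "c3")),
        CRISPRArray("D", ("n4", "n5", "c2", "c3")),
    ]
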