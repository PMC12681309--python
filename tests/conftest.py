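import numpy as np
import pytest

import utemap as u


@pytest.fixture(scope="session")
def protocols():
    """(low-weighting S1 scan, mapping S2 scan) default protocol pair."""
    return u.protocol_pair()


@pytest.fixture(scope="session")
def t2_truth():
    return u.render_truth(u.default_t2star_phantom())


@pytest.fixture(scope="session")
def t1_truth():
    return u.render_truth(u.default_t1_phantom())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
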