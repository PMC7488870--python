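import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160430)


@pytest.fixture(scope="session")
def default_truth():
    from shootzones.synthetic import default_ground_truth

    return default_ground_truth()
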