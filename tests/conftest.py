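import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def printed_series():
    """The 10-sample worked-example series of the DE walkthrough."""
    return np.array([0.1, 2, 3, 2.2, 3.5, 5.7, 2.5, 3.4, 7.3, 1])


@pytest.fixture
def table1_patterns():
    """The nine dispersion patterns of the worked example, in window order."""
    return [(1, 1), (1, 2), (2, 2), (2, 2), (2, 3), (3, 2), (2, 2), (2, 3), (3, 1)]
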