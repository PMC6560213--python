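import warnings

import numpy as np
import pytest

from qti.design import RampSpec, default_prior, make_ramp_design
from qti.epg import TruncationWarning


@pytest.fixture(autouse=True)
def _quiet_truncation():
    # reduced-order simulations in the heavy tests intentionally trade the
    # top-order population for speed; the dedicated warning test re-enables it
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TruncationWarning)
        yield


@pytest.fixture(scope="session")
def ramp_design():
    """The optimized acquisition: 7->70 degree ramp, 260 reps, TE/TR 2/14 ms,
    2 mm slice, initial inversion."""
    return make_ramp_design(RampSpec(alpha_a=7, alpha_b=70))


@pytest.fixture(scope="session")
def brain_prior():
    return default_prior()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
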