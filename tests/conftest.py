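import numpy as np
import pytest

from swimbeam import config
from swimbeam.morphology import BodyModel


@pytest.fixture(scope="session")
def body():
    """Reference larva on a modest grid."""
    return config.reference_body(61)


@pytest.fixture(scope="session")
def uniform_body():
    """Uniform-section beam (simple closed forms), blunt enough that the
    section vanishes only at the exact tips."""
    s = np.linspace(0.0, 4.0e-3, 61)
    u = s / s[-1]
    base = np.sqrt(np.clip(u * (1 - u), 0, None))
    prof = 0.3e-3 * np.minimum(1.0, 4 * base)
    return BodyModel(s=s, width=prof, height=prof, rho_fish=1000.0)


@pytest.fixture(scope="session")
def forward_low():
    """Session-wide low-resolution forward reference at the smallest level."""
    from swimbeam.validation import forward_reference

    res, bdy = forward_reference("0.12", n_s=101, n_d=31,
                                 steps_per_period=200, periods=3.0)
    return res, bdy
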