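import numpy as np
import pytest

from sopquant import IntensityProfile


def make_profile(values, normalized=False):
    """IntensityProfile from raw values with dummy arc positions."""
    values = np.asarray(values, dtype=float)
    return IntensityProfile(
        values=values, arc_positions=np.arange(1.0, values.size + 1), normalized=normalized
    )


@pytest.fixture
def uniform_profile():
    return make_profile(np.full(36, 7.0))


@pytest.fixture
def cosine_profile():
    """I_k = 1 + cos(theta_k), theta_k = 2*pi*k/36: a pure unipolar crescent."""
    k = np.arange(1, 37)
    return make_profile(1.0 + np.cos(2 * np.pi * k / 36))


@pytest.fixture
def cosine2_profile():
    """I_k = 1 + cos(2*theta_k): a pure bipolar (nematic) pattern."""
    k = np.arange(1, 37)
    return make_profile(1.0 + np.cos(2 * 2 * np.pi * k / 36))
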