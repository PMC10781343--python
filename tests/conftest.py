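import numpy as np
import pytest

from romval import BodyTemplate, CameraModel, ProtocolSpec


@pytest.fixture
def template():
    return BodyTemplate()


@pytest.fixture
def protocol():
    return ProtocolSpec()


@pytest.fixture
def identity_camera():
    return CameraModel()


def raised_cosine_series(starts, amps, period, fps, total):
    """Reference pulse-train generator used as an independent oracle in tests."""
    t = np.arange(0.0, total, 1.0 / fps)
    v = np.zeros_like(t)
    for s, a in zip(starts, amps):
        m = (t >= s) & (t <= s + period)
        v[m] = a * 0.5 * (1 - np.cos(2 * np.pi * (t[m] - s) / period))
    return t, v
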