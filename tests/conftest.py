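import numpy as np
import pytest

from ocufit import IRFCurve, TimeAxis, gaussian_irf


@pytest.fixture
def time_axis():
    """Coarse 256-channel axis spanning the 12.5 ns repetition period."""
    return TimeAxis(n_channels=256, channel_width_ps=48.8, rep_period_ns=12.5)


@pytest.fixture
def exact_axis():
    """1000 x 12.5 ps axis: the repetition period is an exact channel count."""
    return TimeAxis(n_channels=1000, channel_width_ps=12.5, rep_period_ns=12.5)


@pytest.fixture
def delta_irf(exact_axis):
    v = np.zeros(exact_axis.n_channels)
    v[0] = 1.0
    return IRFCurve(values=v, time=exact_axis)


@pytest.fixture
def irf(time_axis):
    return gaussian_irf(time_axis, fwhm_ps=172.0, t0_ps=1000.0)
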