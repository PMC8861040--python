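import math

import numpy as np
import pytest

from twodelay import History, Trajectory, TwoDelayCubicModel


@pytest.fixture
def vdp_single_delay():
    """dx/dt = -x(t - pi/2): cos t is an exact solution (marginal oscillator)."""
    return TwoDelayCubicModel(a1=-1.0, a2=0.0, tau1=math.pi / 2)


@pytest.fixture
def steps_model():
    """dx/dt = 2 x(t-1), history 1: piecewise-polynomial exact solution.

    x(t) = 1 + 2t on [0,1] and x(t) = 1 + 2t + 2(t-1)^2 on [1,2], so
    x(1) = 3 and x(2) = 7.
    """
    return TwoDelayCubicModel(a1=2.0, a2=0.0, tau1=1.0)


def analytic_trajectory(func, dfunc, t_end, h):
    """Build a Trajectory directly from samples of an analytic signal."""
    t = np.arange(0.0, t_end + h / 2, h)
    return Trajectory(times=t, values=np.array([func(s) for s in t]),
                      derivs=np.array([dfunc(s) for s in t]), h=h)
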