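import math

import numpy as np
import pytest

import multisync as ms

OMEGA_24 = 2.0 * math.pi / 24.0


@pytest.fixture(scope="session")
def cfg():
    return ms.IntegratorConfig()


@pytest.fixture(scope="session")
def clock():
    return ms.make_goodwin_clock()


@pytest.fixture(scope="session")
def cdk():
    return ms.make_cdk_cycle()


@pytest.fixture(scope="session")
def nf_bi():
    """Birhythmic normal form: stable cycles at r=1 and r=3, both 24 h."""
    return ms.make_normal_form((1.0, 2.0, 3.0), OMEGA_24)


@pytest.fixture(scope="session")
def nf_tri():
    """Trirhythmic normal form: stable cycles at 0.5/1.5/2.5 with shear."""
    return ms.make_normal_form((0.5, 1.0, 1.5, 2.0, 2.5), OMEGA_24, shear=0.01)


@pytest.fixture(scope="session")
def strong_system(clock, cdk):
    """Shipped strong-coupling configuration: robust 1:1 locking."""
    from multisync.fixtures import STRONG_COUPLING

    return ms.make_coupled(clock, cdk, ms.CouplingSpec(**STRONG_COUPLING))


@pytest.fixture(scope="session")
def clock_traj(clock, cfg):
    """Long free-running clock trajectory shared across tests."""
    return ms.integrate(clock, clock.default_state, 0.0, 700.0, cfg)


@pytest.fixture(scope="session")
def converged_states(clock, cdk, cfg):
    """(clock_state, cycle_state) on the free-running attractors."""
    tc = ms.integrate(clock, clock.default_state, 0.0, 600.0, cfg)
    ty = ms.integrate(cdk, cdk.default_state, 0.0, 600.0, cfg)
    return tc.data[-1], ty.data[-1]


def radial_basin_oracle(radii, r0):
    """Predict the attracting radius by sign analysis of the radial flow.

    dr/dt = -k r prod(r^2 - rho_i^2): between consecutive roots the sign
    is constant, so r0 converges to the nearest stable root enclosing its
    interval.  Independent of the 2-D integration path.
    """
    rho = list(radii)
    stable = rho[0::2]
    unstable = rho[1::2]
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    below = [u for u in unstable if u < r0]
    if not below:
        return stable[0]
    k = unstable.index(max(below))
    return stable[k + 1]
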