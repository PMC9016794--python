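"""Frozen calibration constants for the shipped stand-in oscillators.

Both stand-ins expose a global time-scale factor that divides every rate,
so the oscillation period scales exactly linearly with it.  The base
periods below were measured once on the shipped parameter sets (time
scale = 1, LSODA, rtol 1e-10 / atol 1e-12, inter-peak analysis after a
long transient) and are frozen here; the reference time scales follow by
exact rescaling rather than by iterative tuning.
"""

# Free-running period of the clock stand-in at tau = 1 (internal time units).
CLOCK_BASE_PERIOD = 27.4693739

# Free-running period of the Cdk-cycle stand-in at eps = 1.
CDK_BASE_PERIOD = 9.8644510

# Target free-running periods (hours): circadian clock 24 h, cell cycle 19.1 h.
CLOCK_TARGET_PERIOD = 24.0
CDK_TARGET_PERIOD = 19.1

#: Time scale giving the clock stand-in a 24.0 h free-running period.
TAU_REF = CLOCK_TARGET_PERIOD / CLOCK_BASE_PERIOD

#: Time scale giving the Cdk-cycle stand-in a 19.1 h free-running period.
EPS_REF = CDK_TARGET_PERIOD / CDK_BASE_PERIOD
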