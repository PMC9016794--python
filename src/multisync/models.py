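"""Oscillator stand-ins, bidirectional coupling, and periodic forcing.

This module is the synthetic-systems generator of the package.  It builds
the autonomous limit-cycle oscillators that every downstream analysis
stage (integration, rhythm analysis, censuses) operates on:

* an analytic normal-form oscillator with an arbitrary odd number of
  invariant circles, used as an exactly solvable oracle for multi-stable
  limit cycles (birhythmicity, trirhythmicity, hysteresis);
* a 3-variable negative-feedback "Goodwin" clock stand-in with a
  free-running period calibrated to 24 h, carrying a mitotic-repression
  input port;
* a 4-variable relaxation-type Cdk-cycle stand-in (cyclin, Cdk1-like
  activity, degradation activator, Wee1-like inhibitor) with a global
  time-scale factor ``eps`` calibrated so the free-running period is
  19.1 h, carrying a Wee1-induction input port;
* the bidirectional coupling of a clock model and a cycle model
  (clock induces Wee1 with maximum rate ``v_sw``; Cdk1 represses clock
  transcription with inhibition constant ``K_ICdk1``);
* periodically forced (non-autonomous) variants of any model.

External oscillator models — for instance a full mechanistic
clock/cell-cycle system defined elsewhere — plug into every protocol in
the package by constructing an :class:`OscillatorModel` (or registering a
builder in :data:`registry`); nothing downstream depends on the shipped
equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from ._calibration import (
    CDK_BASE_PERIOD,
    CDK_TARGET_PERIOD,
    CLOCK_BASE_PERIOD,
    CLOCK_TARGET_PERIOD,
    EPS_REF,
    TAU_REF,
)
from .errors import ConstructionError, ValidationError

__all__ = [
    "OscillatorModel",
    "CouplingSpec",
    "CoupledSystem",
    "ForcingSpec",
    "make_normal_form",
    "make_radial_hysteresis",
    "make_goodwin_clock",
    "make_cdk_cycle",
    "make_coupled",
    "make_forced",
    "registry",
    "register_model",
]


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OscillatorModel:
    """A named autonomous (or periodically forced) ODE system.

    Parameters
    ----------
    name
        Short identifier, echoed in manifests and provenance records.
    var_labels
        One label per state variable.
    units
        Units per state variable ("uM" for concentrations, "" for
        dimensionless quantities).  Non-negativity is enforced only for
        concentration variables.
    params
        Parameter name -> value.  The right-hand side reads parameters at
        call time, so :meth:`with_params` produces an independent model.
    param_units
        Parameter name -> unit string (informational).
    time_scale
        Positive factor dividing every rate; the oscillation period
        scales exactly linearly with it.
    rhs
        ``rhs(t, y, ports, params) -> rates`` returning the *unscaled*
        rate vector; the division by ``time_scale`` is applied centrally
        by :meth:`derivative`.
    input_ports
        Exogenous signal name -> neutral default.  With every port at its
        neutral default the system is autonomous.
    output_ports
        Readout port name -> state-variable label.
    nominal_period
        Free-running period metadata in hours, if known.
    default_state
        A state inside the basin of the documented default attractor,
        used when a protocol needs "the shipped initial state".
    aux_outputs
        Extra labeled channels ``f(t, y, params) -> value`` recorded
        alongside the state (e.g. the forcing trace of a forced model).
    breakpoints
        ``f(t0, t1, params) -> times`` listing interior times where the
        right-hand side is discontinuous; the integrator stops and
        restarts there.
    """

    name: str
    var_labels: tuple[str, ...]
    units: tuple[str, ...]
    params: Mapping[str, float]
    rhs: Callable
    time_scale: float = 1.0
    param_units: Mapping[str, str] = field(default_factory=dict)
    input_ports: Mapping[str, float] = field(default_factory=dict)
    output_ports: Mapping[str, str] = field(default_factory=dict)
    nominal_period: float | None = None
    default_state: tuple[float, ...] | None = None
    aux_outputs: Mapping[str, Callable] = field(default_factory=dict)
    breakpoints: Callable | None = None

    def __post_init__(self):
        if self.n_vars < 2:
            raise ValidationError(f"{self.name}: need at least 2 state variables")
        if len(self.units) != self.n_vars:
            raise ValidationError(f"{self.name}: units/var_labels length mismatch")
        if not (self.time_scale > 0):
            raise ValidationError(f"{self.name}: time_scale must be positive")
        for port, var in self.output_ports.items():
            if var not in self.var_labels:
                raise ValidationError(
                    f"{self.name}: output port {port!r} references unknown variable {var!r}"
                )
        if self.default_state is not None and len(self.default_state) != self.n_vars:
            raise ValidationError(f"{self.name}: default_state dimension mismatch")

    # -- basic introspection ------------------------------------------------

    @property
    def n_vars(self) -> int:
        return len(self.var_labels)

    def var_index(self, label: str) -> int:
        try:
            return self.var_labels.index(label)
        except ValueError:
            raise ValidationError(f"{self.name}: unknown variable {label!r}") from None

    def readout_index(self, port: str) -> int:
        if port not in self.output_ports:
            raise ValidationError(f"{self.name}: unknown output port {port!r}")
        return self.var_index(self.output_ports[port])

    # -- evaluation ---------------------------------------------------------

    def derivative(self, t: float, y, ports: Mapping[str, float] | None = None):
        """Rate of change at ``(t, y)``, with absent ports at their neutral defaults."""
        if ports is None:
            ports = self.input_ports
        elif self.input_ports:
            merged = dict(self.input_ports)
            merged.update(ports)
            ports = merged
        dy = self.rhs(t, y, ports, self.params)
        if self.time_scale != 1.0:
            return [v / self.time_scale for v in dy]
        return dy

    # -- derived models -----------------------------------------------------

    def with_params(self, **overrides: float) -> "OscillatorModel":
        unknown = set(overrides) - set(self.params)
        if unknown:
            raise ValidationError(f"{self.name}: unknown parameters {sorted(unknown)}")
        params = dict(self.params)
        params.update(overrides)
        return replace(self, params=params)

    def with_time_scale(self, time_scale: float) -> "OscillatorModel":
        if not (time_scale > 0):
            raise ValidationError("time_scale must be positive")
        return replace(self, time_scale=time_scale)

    # -- provenance ---------------------------------------------------------

    def manifest(self) -> dict:
        """Serializable record of the constructed model."""
        return {
            "name": self.name,
            "n_vars": self.n_vars,
            "var_labels": list(self.var_labels),
            "units": list(self.units),
            "params": {k: float(v) for k, v in sorted(self.params.items())},
            "param_units": dict(sorted(self.param_units.items())),
            "time_scale": float(self.time_scale),
            "input_ports": {k: float(v) for k, v in sorted(self.input_ports.items())},
            "output_ports": dict(sorted(self.output_ports.items())),
            "nominal_period": None if self.nominal_period is None else float(self.nominal_period),
            "default_state": None if self.default_state is None
            else [float(v) for v in self.default_state],
        }


@dataclass(frozen=True)
class CouplingSpec:
    """Bidirectional clock <-> cell-cycle coupling strengths.

    ``v_sw`` is the maximum clock-driven Wee1-induction rate (uM/h in the
    cycle model's internal rate units) and ``K_w``/``h_w`` shape the Hill
    dependence of that induction on the clock readout.  ``K_ICdk1`` is
    the inhibition constant of the Cdk1-dependent mitotic repression of
    clock transcription (uM; smaller = stronger repression) with Hill
    exponent ``g_r``.  ``t_c`` is the time at which the bidirectional
    coupling switches on; before it, both oscillators run free.
    """

    v_sw: float
    K_ICdk1: float
    h_w: float = 4.0
    g_r: float = 2.0
    K_w: float = 0.4
    clock_readout: str = "clock_readout"
    cycle_readout: str = "cdk1_like"
    t_c: float = 0.0

    def __post_init__(self):
        if self.v_sw < 0:
            raise ValidationError("v_sw must be >= 0")
        if not (self.K_ICdk1 > 0):
            raise ValidationError("K_ICdk1 must be > 0")
        if self.h_w < 1 or self.g_r < 1:
            raise ValidationError("Hill exponents h_w and g_r must be >= 1")
        if not (self.K_w > 0):
            raise ValidationError("K_w must be > 0")

    def manifest(self) -> dict:
        return {
            "v_sw": float(self.v_sw),
            "K_ICdk1": float(self.K_ICdk1),
            "h_w": float(self.h_w),
            "g_r": float(self.g_r),
            "K_w": float(self.K_w),
            "clock_readout": self.clock_readout,
            "cycle_readout": self.cycle_readout,
            "t_c": float(self.t_c),
        }


class CoupledSystem:
    """Two oscillators joined by a :class:`CouplingSpec`.

    The composed state is the concatenation of the clock state and the
    cycle state.  While the coupling is inactive both sub-systems evolve
    autonomously (ports at neutral defaults); once active, the cycle's
    Wee1-induction port receives ``v_sw * S^h_w / (K_w^h_w + S^h_w)``
    with ``S`` the clock readout, and the clock's mitotic-repression
    port receives ``K_ICdk1^g_r / (K_ICdk1^g_r + A^g_r)`` with ``A`` the
    Cdk1-like readout.  Setting ``v_sw = 0`` and ``K_ICdk1 -> inf``
    recovers the uncoupled pair exactly.
    """

    #: port names the coupling drives on each side
    CLOCK_PORT = "mitotic_repression"
    CYCLE_PORT = "wee1_induction"

    def __init__(self, clock: OscillatorModel, cycle: OscillatorModel,
                 coupling: CouplingSpec):
        if self.CLOCK_PORT not in clock.input_ports:
            raise ValidationError(
                f"clock model {clock.name!r} lacks input port {self.CLOCK_PORT!r}")
        if self.CYCLE_PORT not in cycle.input_ports:
            raise ValidationError(
                f"cycle model {cycle.name!r} lacks input port {self.CYCLE_PORT!r}")
        self._i_clock_readout = clock.readout_index(coupling.clock_readout)
        self._i_cycle_readout = cycle.readout_index(coupling.cycle_readout)
        self.clock = clock
        self.cycle = cycle
        self.coupling = coupling
        clash = set(clock.var_labels) & set(cycle.var_labels)
        if clash:
            labels = tuple(f"{clock.name}.{v}" for v in clock.var_labels) + tuple(
                f"{cycle.name}.{v}" for v in cycle.var_labels)
        else:
            labels = clock.var_labels + cycle.var_labels
        self.var_labels: tuple[str, ...] = labels
        self.units: tuple[str, ...] = clock.units + cycle.units
        self.n_vars = clock.n_vars + cycle.n_vars
        self._split = clock.n_vars
        # hot-path caches: the coupled derivative runs inside the
        # integrator loop, so avoid rebuilding port dicts per call
        self._clock_ports = dict(clock.input_ports)
        self._cycle_ports = dict(cycle.input_ports)
        self._Kwh = coupling.K_w ** coupling.h_w
        self._Kg = coupling.K_ICdk1 ** coupling.g_r

    def derivative(self, t: float, y, active: bool):
        yc = y[: self._split]
        yy = y[self._split:]
        cp = self.coupling
        clock, cycle = self.clock, self.cycle
        if active:
            S = yc[self._i_clock_readout]
            A = yy[self._i_cycle_readout]
            Sh = (S if S > 0.0 else 0.0) ** cp.h_w
            u = cp.v_sw * Sh / (self._Kwh + Sh)
            R = self._Kg / (self._Kg + (A if A > 0.0 else 0.0) ** cp.g_r)
        else:
            u = cycle.input_ports[self.CYCLE_PORT]
            R = clock.input_ports[self.CLOCK_PORT]
        self._clock_ports[self.CLOCK_PORT] = R
        self._cycle_ports[self.CYCLE_PORT] = u
        d1 = clock.rhs(t, yc, self._clock_ports, clock.params)
        d2 = cycle.rhs(t, yy, self._cycle_ports, cycle.params)
        ts1, ts2 = clock.time_scale, cycle.time_scale
        return [v / ts1 for v in d1] + [v / ts2 for v in d2]

    def default_state(self) -> list[float]:
        if self.clock.default_state is None or self.cycle.default_state is None:
            raise ValidationError("both sub-models need a default_state")
        return list(self.clock.default_state) + list(self.cycle.default_state)

    def readout_labels(self) -> tuple[str, str]:
        """Composed-trajectory labels of (clock readout, cycle readout)."""
        return (self.var_labels[self._i_clock_readout],
                self.var_labels[self._split + self._i_cycle_readout])

    def manifest(self) -> dict:
        return {
            "clock": self.clock.manifest(),
            "cycle": self.cycle.manifest(),
            "coupling": self.coupling.manifest(),
        }


@dataclass(frozen=True)
class ForcingSpec:
    """Periodic modulation of one named model parameter.

    ``square``: the parameter sits at a high level for ``duty`` of each
    cycle and at a low level otherwise.  ``amplitude`` is in parameter
    units; by default the cycle-average is preserved (high = p0 +
    amplitude, low = p0 - amplitude*duty/(1-duty)).

    ``sinusoid``: p(t) = p0 * (1 + amplitude * sin(2*pi*t/period)) with
    relative ``amplitude``; values are clipped at zero only when
    ``clip=True``, otherwise an amplitude > 1 is rejected.
    """

    target: str
    kind: str
    period: float
    amplitude: float
    duty: float = 0.5
    clip: bool = False

    def __post_init__(self):
        if self.kind not in ("square", "sinusoid"):
            raise ValidationError(f"unknown waveform kind {self.kind!r}")
        if not (self.period > 0):
            raise ValidationError("forcing period must be > 0")
        if self.amplitude < 0:
            raise ValidationError("forcing amplitude must be >= 0")
        if self.kind == "square" and not (0.0 < self.duty < 1.0):
            raise ValidationError("square duty fraction must lie in (0, 1)")

    def manifest(self) -> dict:
        return {
            "target": self.target,
            "kind": self.kind,
            "period": float(self.period),
            "amplitude": float(self.amplitude),
            "duty": float(self.duty),
            "clip": bool(self.clip),
        }


# ---------------------------------------------------------------------------
# analytic normal-form oscillators
# ---------------------------------------------------------------------------

def _radial_rhs(t, y, ports, p):
    """Planar system with radial polynomial dr/dt = r*g(r^2) and
    angular speed omega0 + beta*r^2."""
    x, yy = y[0], y[1]
    s = x * x + yy * yy
    g = -p["k"]
    m = int(p["m"])
    for i in range(1, m + 1):
        rho = p[f"rho{i}"]
        g *= s - rho * rho
    w = p["omega0"] + p["beta"] * s
    return [g * x - w * yy, g * yy + w * x]


def make_normal_form(radii: Sequence[float], omega0: float, shear: float = 0.0,
                     relax: float = 1e-2) -> OscillatorModel:
    """Planar oscillator with invariant circles at the given radii.

    The radial dynamics are ``dr/dt = -k * r * prod_i (r^2 - rho_i^2)``
    and the angular dynamics ``dtheta/dt = omega0 + shear * r^2``.  With
    an odd number of strictly increasing radii, the circles at
    ``rho_1, rho_3, ...`` are stable limit cycles, those at
    ``rho_2, rho_4, ...`` unstable, and the origin is unstable; the cycle
    at radius ``rho`` has period ``2*pi / (omega0 + shear * rho^2)``
    exactly.  This is the analytic oracle for every multi-rhythmicity
    protocol in the package.
    """
    radii = tuple(float(r) for r in radii)
    m = len(radii)
    if m % 2 == 0 or m == 0:
        raise ValidationError("need an odd number of radii")
    if any(r <= 0 for r in radii) or any(
            b <= a for a, b in zip(radii, radii[1:])):
        raise ValidationError("radii must be strictly increasing and positive")
    if not (omega0 > 0):
        raise ValidationError("omega0 must be > 0")
    if not (relax > 0):
        raise ValidationError("relax must be > 0")
    params = {"omega0": float(omega0), "beta": float(shear),
              "k": float(relax), "m": float(m)}
    for i, r in enumerate(radii, start=1):
        params[f"rho{i}"] = r
    return OscillatorModel(
        name="normal_form",
        var_labels=("x", "y"),
        units=("", ""),
        params=params,
        rhs=_radial_rhs,
        output_ports={"clock_readout": "x"},
        nominal_period=2.0 * math.pi / (omega0 + shear * radii[0] ** 2),
        default_state=(radii[0], 0.0),
        param_units={"omega0": "rad/h", "beta": "rad/h", "k": "1/h"},
    )


def _radial_hysteresis_rhs(t, y, ports, p):
    x, yy = y[0], y[1]
    s = x * x + yy * yy
    g = -p["k"] * ((s - 1.0) * ((s - p["c"]) ** 2 - p["mu"]))
    w = p["omega0"]
    return [g * x - w * yy, g * yy + w * x]


def make_radial_hysteresis(c: float = 4.0, mu: float = 1.0, relax: float = 1e-2,
                           omega0: float = 2.0 * math.pi / 24.0) -> OscillatorModel:
    """Planar fixture with radial flow ``dr/dt = -k r (r^2-1)((r^2-c)^2 - mu)``.

    For ``mu`` in (0, (c-1)^2] the unit cycle coexists with a stable
    outer cycle at radius ``sqrt(c + sqrt(mu))`` (separated by an
    unstable cycle at ``sqrt(c - sqrt(mu))``); for ``mu <= 0`` only the
    unit cycle is stable.  Ramping ``mu`` back and forth across this
    window is the closed-form hysteresis oracle.
    """
    if not (c > 1):
        raise ValidationError("c must exceed 1")
    return OscillatorModel(
        name="radial_hysteresis",
        var_labels=("x", "y"),
        units=("", ""),
        params={"c": float(c), "mu": float(mu), "k": float(relax),
                "omega0": float(omega0)},
        rhs=_radial_hysteresis_rhs,
        nominal_period=2.0 * math.pi / omega0,
        default_state=(1.0, 0.0),
    )


# ---------------------------------------------------------------------------
# clock stand-in
# ---------------------------------------------------------------------------

#: Shipped clock parameter set (negative transcriptional feedback,
#: Michaelian degradations, Hill-repressed synthesis).
CLOCK_PARAMS: dict[str, float] = {
    "v1": 0.7,   # uM/h  maximal clock mRNA synthesis
    "K1": 1.0,   # uM    repression threshold of nuclear repressor
    "n": 6.0,    # -     Hill exponent of transcriptional repression
    "v2": 0.35,  # uM/h  maximal mRNA degradation
    "K2": 1.0,   # uM
    "k3": 0.7,   # 1/h   translation
    "v4": 0.35,  # uM/h  maximal protein degradation
    "K4": 1.0,   # uM
    "k5": 0.7,   # 1/h   nuclear import / activation
    "v6": 0.35,  # uM/h  maximal repressor degradation
    "K6": 1.0,   # uM
}


def _goodwin_rhs(t, y, ports, p):
    M, P, I = y[0], y[1], y[2]
    R = ports["mitotic_repression"]
    Kn = p["K1"] ** p["n"]
    dM = p["v1"] * Kn / (Kn + max(I, 0.0) ** p["n"]) * R - p["v2"] * M / (p["K2"] + M)
    dP = p["k3"] * M - p["v4"] * P / (p["K4"] + P)
    dI = p["k5"] * P - p["v6"] * I / (p["K6"] + I)
    return [dM, dP, dI]


def make_goodwin_clock(time_scale: float = TAU_REF,
                       params: Mapping[str, float] | None = None,
                       self_check: bool = True) -> OscillatorModel:
    """3-variable negative-feedback circadian clock stand-in.

    Clock mRNA ``M`` is synthesised under Hill repression by the nuclear
    repressor ``I`` and multiplied by the mitotic-repression input port
    (neutral default 1); cytosolic protein ``P`` is made from ``M`` and
    the repressor from ``P``; all degradations are Michaelian.  Output
    port ``"clock_readout"`` exposes ``P`` (the BMAL1-proxy used to drive
    Wee1 induction when coupled).  With the default ``time_scale`` the
    free-running period is 24.0 h.
    """
    if not (time_scale > 0):
        raise ValidationError("time_scale (tau) must be > 0")
    p = dict(CLOCK_PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValidationError(f"unknown clock parameters {sorted(unknown)}")
        p.update(params)
    model = OscillatorModel(
        name="goodwin_clock",
        var_labels=("M", "P", "I"),
        units=("uM", "uM", "uM"),
        params=p,
        rhs=_goodwin_rhs,
        time_scale=time_scale,
        input_ports={"mitotic_repression": 1.0},
        output_ports={"clock_readout": "P"},
        nominal_period=CLOCK_BASE_PERIOD * time_scale,
        default_state=(0.1, 0.2, 0.3),
        param_units={k: ("uM/h" if k.startswith("v") else
                         "1/h" if k.startswith("k") else
                         "uM" if k.startswith("K") else "")
                     for k in p},
    )
    if self_check:
        _oscillation_self_check(model)
    return model


# ---------------------------------------------------------------------------
# Cdk-cycle stand-in
# ---------------------------------------------------------------------------

#: Shipped cell-cycle parameter set (cyclin-driven Cdk1 activation with
#: Wee1-sensitive inactivation and an APC-like degradation activator).
CDK_PARAMS: dict[str, float] = {
    "vc": 0.05,   # uM/h  constant cyclin synthesis
    "vd": 0.25,   # uM/h  maximal cyclin degradation (activated by X)
    "Kd": 0.02,   # uM
    "kdc": 0.01,  # 1/h   basal cyclin decay
    "VM1": 4.0,   # uM/h  maximal Cdk1 activation
    "Kc": 0.5,    # uM    cyclin half-activation of Cdk1
    "K1": 0.05,   # -     activation threshold (fraction units)
    "V2": 1.5,    # uM/h  basal Cdk1 inactivation
    "K2": 0.05,   # -
    "kw": 1.0,    # 1/h   Wee1 contribution to Cdk1 inactivation
    "VM3": 1.0,   # uM/h  maximal activation of the degradation activator
    "K3": 0.05,   # -
    "V4": 0.5,    # uM/h  inactivation of the degradation activator
    "K4": 0.05,   # -
    "vw0": 0.05,  # uM/h  basal Wee1 synthesis
    "kdw": 0.5,   # 1/h   Wee1 decay
}


def _cdk_rhs(t, y, ports, p):
    C, A, X, W = y[0], y[1], y[2], y[3]
    u = ports["wee1_induction"]
    dC = p["vc"] - p["vd"] * X * C / (p["Kd"] + C) - p["kdc"] * C
    V1 = p["VM1"] * C / (p["Kc"] + C)
    dA = V1 * (1.0 - A) / (p["K1"] + 1.0 - A) \
        - (p["V2"] + p["kw"] * W) * A / (p["K2"] + A)
    dX = p["VM3"] * A * (1.0 - X) / (p["K3"] + 1.0 - X) \
        - p["V4"] * X / (p["K4"] + X)
    dW = p["vw0"] + u - p["kdw"] * W
    return [dC, dA, dX, dW]


def make_cdk_cycle(eps: float = EPS_REF,
                   params: Mapping[str, float] | None = None,
                   self_check: bool = True) -> OscillatorModel:
    """4-variable relaxation-type mitotic oscillator stand-in.

    Cyclin ``C`` accumulates at a constant rate and is degraded when the
    activator ``X`` is on; Cdk1-like activity ``A`` (total pool 1 uM) is
    switched on by cyclin through a Michaelian step and switched off at a
    rate increased by the Wee1-like inhibitor ``W``; ``X`` is activated
    by ``A``; ``W`` has basal synthesis plus whatever induction arrives
    on the ``"wee1_induction"`` input port (neutral default 0) and decays
    first order.  Every rate is divided by ``eps``; with the default
    ``eps`` the free-running period is 19.1 h.  Output port
    ``"cdk1_like"`` exposes ``A``.
    """
    if not (eps > 0):
        raise ValidationError("eps must be > 0")
    p = dict(CDK_PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValidationError(f"unknown cycle parameters {sorted(unknown)}")
        p.update(params)
    model = OscillatorModel(
        name="cdk_cycle",
        var_labels=("C", "A", "X", "W"),
        units=("uM", "uM", "", "uM"),
        params=p,
        rhs=_cdk_rhs,
        time_scale=eps,
        input_ports={"wee1_induction": 0.0},
        output_ports={"cdk1_like": "A"},
        nominal_period=CDK_BASE_PERIOD * eps,
        default_state=(0.1, 0.1, 0.1, 0.1),
        param_units={k: ("uM/h" if k[0] in "vV" else
                         "1/h" if k.startswith("k") else "uM")
                     for k in p},
    )
    if self_check:
        _oscillation_self_check(model)
    return model


# ---------------------------------------------------------------------------
# construction-time oscillation self-check
# ---------------------------------------------------------------------------

_CHECKED: set[tuple] = set()


def _oscillation_self_check(model: OscillatorModel) -> None:
    """Verify the shipped stand-in oscillates with the advertised period.

    Integrates a few nominal periods past a transient and counts peaks of
    the first readout variable.  Results are memoised per parameter set,
    so repeated default constructions pay the cost once per process.
    """
    key = (model.name, model.time_scale, tuple(sorted(model.params.items())))
    if key in _CHECKED:
        return
    from .engine import IntegratorConfig, integrate  # local import: avoid cycle

    T = model.nominal_period or 24.0
    cfg = IntegratorConfig(rtol=1e-6, atol=1e-8, dt_out=T / 200.0)
    traj = integrate(model, model.default_state, 0.0, 40.0 * T, cfg)
    var = next(iter(model.output_ports.values()), model.var_labels[0])
    x = traj[var]
    tail = x[traj.n_samples // 2:]
    if tail.max() - tail.min() < 1e-3:
        raise ConstructionError(
            f"{model.name}: self-check found no sustained oscillation "
            f"(late range {tail.max() - tail.min():.2e})")
    from .rhythm import estimate_period

    est = estimate_period(traj, var, discard=20.0 * T)
    lo, hi = 0.8 * T, 1.2 * T
    if not (lo <= est.period <= hi):
        raise ConstructionError(
            f"{model.name}: self-check period {est.period:.2f} h outside "
            f"[{lo:.2f}, {hi:.2f}] h around the advertised {T:.2f} h")
    _CHECKED.add(key)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def make_coupled(clock: OscillatorModel, cycle: OscillatorModel,
                 coupling: CouplingSpec) -> CoupledSystem:
    """Join a clock model and a cycle model bidirectionally.

    See :class:`CoupledSystem` for the functional form of the two
    coupling arms.
    """
    return CoupledSystem(clock, cycle, coupling)


def make_forced(model: OscillatorModel, forcing: ForcingSpec) -> OscillatorModel:
    """Non-autonomous variant of ``model`` with one parameter varying periodically."""
    if forcing.target not in model.params:
        raise ValidationError(
            f"{model.name}: forcing target {forcing.target!r} is not a parameter")
    p0 = float(model.params[forcing.target])
    if forcing.kind == "sinusoid":
        if forcing.amplitude > 1.0 and not forcing.clip:
            raise ValidationError(
                "sinusoid amplitude > 1 drives the parameter negative; "
                "enable clip=True to clip at zero")

        def value(t):
            v = p0 * (1.0 + forcing.amplitude * math.sin(2.0 * math.pi * t / forcing.period))
            return max(v, 0.0) if forcing.clip else v

        breakpoints = None
    else:  # square
        high = p0 + forcing.amplitude
        low = p0 - forcing.amplitude * forcing.duty / (1.0 - forcing.duty)
        if low < 0:
            raise ValidationError(
                "square forcing drives the parameter negative "
                f"(low level {low:.4g})")

        def value(t):
            phase = (t / forcing.period) % 1.0
            return high if phase < forcing.duty else low

        def breakpoints(t0, t1, params):
            edges = []
            n0 = math.floor(t0 / forcing.period)
            n1 = math.ceil(t1 / forcing.period) + 1
            for n in range(n0, n1):
                for e in (n * forcing.period, (n + forcing.duty) * forcing.period):
                    if t0 < e < t1:
                        edges.append(e)
            return edges

    base_rhs = model.rhs
    target = forcing.target

    def forced_rhs(t, y, ports, params):
        pp = dict(params)
        pp[target] = value(t)
        return base_rhs(t, y, ports, pp)

    aux = dict(model.aux_outputs)
    aux["forcing"] = lambda t, y, params: value(t)
    return replace(
        model,
        name=f"{model.name}+forced[{forcing.target}]",
        rhs=forced_rhs,
        aux_outputs=aux,
        breakpoints=breakpoints,
    )


# ---------------------------------------------------------------------------
# model registry (plugin contract)
# ---------------------------------------------------------------------------

#: Name -> builder.  Builders accept keyword overrides and return an
#: OscillatorModel.  External packages register their own systems here
#: (e.g. a full mechanistic clock/cell-cycle model) and every protocol in
#: this package — integration, censuses, diagrams, entrainment maps —
#: works on them unchanged.
registry: dict[str, Callable[..., OscillatorModel]] = {}


def register_model(name: str, builder: Callable[..., OscillatorModel],
                   overwrite: bool = False) -> None:
    if name in registry and not overwrite:
        raise ValidationError(f"model {name!r} already registered")
    registry[name] = builder


registry.update({
    "normal_form": make_normal_form,
    "radial_hysteresis": make_radial_hysteresis,
    "goodwin_clock": make_goodwin_clock,
    "cdk_cycle": make_cdk_cycle,
})
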