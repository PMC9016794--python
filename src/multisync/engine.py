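"""Deterministic ODE integration with onset events and pulse perturbations.

Integration uses LSODA (switching Adams/BDF, stiff-capable) through
``scipy.integrate.odeint``, sampled on a uniform output grid.  Events —
the coupling-onset time and instantaneous pulses — are handled by
stopping the integrator and restarting it from the event state, never by
a discontinuous right-hand side inside one adaptive step, so the
integrator's error control is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

from .errors import IntegrationError, ValidationError
from .models import CoupledSystem, OscillatorModel

__all__ = ["IntegratorConfig", "Trajectory", "PulseSpec",
           "integrate", "integrate_with_onset", "apply_pulse"]


@dataclass(frozen=True)
class IntegratorConfig:
    """Tolerances and output sampling for the integrator."""

    rtol: float = 1e-8
    atol: float = 1e-10
    dt_out: float = 0.05   # h; matches the 0.05 h protocol granularity
    method: str = "lsoda"
    max_step: float = 0.0  # 0 = no cap on the internal step

    def __post_init__(self):
        if not (self.rtol > 0 and self.atol > 0):
            raise ValidationError("tolerances must be positive")
        if not (self.dt_out > 0):
            raise ValidationError("dt_out must be positive")
        if self.method != "lsoda":
            raise ValidationError(f"unsupported method {self.method!r}")

    def manifest(self) -> dict:
        return {"rtol": self.rtol, "atol": self.atol, "dt_out": self.dt_out,
                "method": self.method, "max_step": self.max_step}


@dataclass(frozen=True)
class PulseSpec:
    """Instantaneous additive perturbation of one state variable.

    Either ``time`` (absolute, h) or ``phase`` (fraction of the current
    period, resolved by the caller) fixes when the pulse is applied.
    """

    variable: str
    magnitude: float
    time: float | None = None
    phase: float | None = None

    def __post_init__(self):
        if (self.time is None) == (self.phase is None):
            raise ValidationError("specify exactly one of time or phase")

    def manifest(self) -> dict:
        return {"variable": self.variable, "magnitude": float(self.magnitude),
                "time": self.time, "phase": self.phase}


class Trajectory:
    """Uniformly sampled multivariate time series with provenance.

    Columns are the model's state variables followed by any auxiliary
    outputs (e.g. a forcing trace).  ``provenance`` records the model
    manifest, integrator configuration and applied events so a run can be
    reproduced exactly.
    """

    def __init__(self, t0: float, dt_out: float, data: np.ndarray,
                 var_labels: Sequence[str], provenance: dict | None = None):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 2:
            raise ValidationError("trajectory needs >= 2 samples")
        if data.shape[1] != len(var_labels):
            raise ValidationError("label/column count mismatch")
        if not np.all(np.isfinite(data)):
            raise ValidationError("trajectory contains non-finite values")
        self.t0 = float(t0)
        self.dt_out = float(dt_out)
        self.data = data
        self.var_labels = tuple(var_labels)
        self.provenance = provenance or {}

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt_out * np.arange(self.n_samples)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt_out * (self.n_samples - 1)

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.data[:, self.var_labels.index(label)]
        except ValueError:
            raise ValidationError(f"unknown variable {label!r}") from None

    def state_at(self, time: float) -> np.ndarray:
        """State row nearest to ``time`` (must lie on the sample grid)."""
        i = int(round((time - self.t0) / self.dt_out))
        if not (0 <= i < self.n_samples):
            raise ValidationError(f"time {time} outside trajectory")
        if abs(self.t0 + i * self.dt_out - time) > 1e-9 * max(1.0, abs(time)):
            raise ValidationError(f"time {time} not on the sample grid")
        return self.data[i].copy()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.data, index=pd.Index(self.t, name="time_h"),
                            columns=list(self.var_labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _output_grid(t0: float, t_end: float, dt: float) -> np.ndarray:
    n = int(round((t_end - t0) / dt))
    if abs(t0 + n * dt - t_end) > 1e-9 * max(1.0, abs(t_end)):
        n = int(np.floor((t_end - t0) / dt + 1e-12))
    return t0 + dt * np.arange(n + 1)

_ODEINT_KW = dict(mxstep=100000)


def _integrate_segments(fun, y0, grid: np.ndarray, breaks: Sequence[float],
                        cfg: IntegratorConfig) -> np.ndarray:
    """LSODA over [grid[0], grid[-1]] with stop-and-restart at ``breaks``.

    Returns states sampled at every grid point.
    """
    hmax = cfg.max_step if cfg.max_step > 0 else 0.0
    edges = [grid[0]] + sorted(b for b in breaks if grid[0] < b < grid[-1]) \
        + [grid[-1]]
    out = np.empty((len(grid), len(y0)))
    y = np.asarray(y0, dtype=float)
    out[0] = y
    pos = 1
    for a, b in zip(edges, edges[1:]):
        sub = grid[(grid > a) & (grid <= b)]
        ts = np.concatenate(([a], sub))
        if ts[-1] < b - 1e-12 * max(1.0, abs(b)):
            ts = np.concatenate((ts, [b]))
        res = odeint(fun, y, ts, rtol=cfg.rtol, atol=cfg.atol, hmax=hmax,
                     tfirst=True, **_ODEINT_KW)
        if not np.all(np.isfinite(res)):
            bad = np.where(~np.all(np.isfinite(res), axis=1))[0][0]
            raise IntegrationError(
                "non-finite state during integration",
                last_valid_time=float(ts[max(bad - 1, 0)]))
        take = res[1:1 + len(sub)]
        out[pos:pos + len(sub)] = take
        y = res[-1]
        pos += len(sub)
    if pos != len(grid):
        raise IntegrationError("internal sampling bookkeeping error")
    return out


def _check_nonneg(model_units: Sequence[str], labels: Sequence[str],
                  data: np.ndarray, atol: float) -> None:
    for j, (lab, unit) in enumerate(zip(labels, model_units)):
        if unit == "uM":
            mn = data[:, j].min()
            if mn < -10.0 * atol:
                raise IntegrationError(
                    f"concentration {lab!r} became negative ({mn:.3e})")


def _append_aux(model: OscillatorModel, grid: np.ndarray,
                states: np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    labels = model.var_labels
    if not model.aux_outputs:
        return states, labels
    cols = [states]
    for name, fn in model.aux_outputs.items():
        cols.append(np.array([fn(t, y, model.params)
                              for t, y in zip(grid, states)])[:, None])
        labels = labels + (name,)
    return np.hstack(cols), labels


def integrate(model: OscillatorModel, y0: Sequence[float], t0: float,
              t_end: float, cfg: IntegratorConfig | None = None) -> Trajectory:
    """Integrate an oscillator model with all input ports at their neutral defaults.

    Repeated calls with identical inputs produce identical output in the
    same environment (LSODA is deterministic).
    """
    cfg = cfg or IntegratorConfig()
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (model.n_vars,):
        raise ValidationError(
            f"y0 has dimension {y0.shape}, model {model.name!r} expects {model.n_vars}")
    if not (t_end > t0):
        raise ValidationError("t_end must exceed t0")
    grid = _output_grid(t0, t_end, cfg.dt_out)
    breaks = model.breakpoints(t0, t_end, model.params) if model.breakpoints else []
    states = _integrate_segments(model.derivative, y0, grid, breaks, cfg)
    _check_nonneg(model.units, model.var_labels, states, cfg.atol)
    data, labels = _append_aux(model, grid, states)
    prov = {"model": model.manifest(), "integrator": cfg.manifest(),
            "t0": float(t0), "t_end": float(t_end)}
    return Trajectory(t0, cfg.dt_out, data, labels, prov)


def integrate_with_onset(system: CoupledSystem, y0_clock: Sequence[float],
                         y0_cycle: Sequence[float], t_end: float,
                         cfg: IntegratorConfig | None = None,
                         t0: float = 0.0) -> Trajectory:
    """Integrate a coupled pair whose coupling switches on at ``t_c``.

    Before the onset time ``system.coupling.t_c`` both oscillators evolve
    autonomously; integration stops exactly at ``t_c`` and restarts with
    the coupling terms active.
    """
    cfg = cfg or IntegratorConfig()
    t_c = system.coupling.t_c
    if not (t0 <= t_c <= t_end):
        raise ValidationError(f"t_c={t_c} outside [{t0}, {t_end}]")
    y0 = np.concatenate([np.asarray(y0_clock, float), np.asarray(y0_cycle, float)])
    if len(y0) != system.n_vars:
        raise ValidationError("initial state dimension mismatch")
    grid = _output_grid(t0, t_end, cfg.dt_out)
    pre = grid[grid <= t_c + 1e-12]
    if t_c > t0:
        ts = pre if abs(pre[-1] - t_c) < 1e-12 else np.concatenate((pre, [t_c]))
        free = _integrate_segments(
            lambda t, y: system.derivative(t, y, active=False), y0, ts, [], cfg)
        y_at_tc = free[-1]
        states_pre = free[: len(pre)]
    else:
        y_at_tc = y0
        states_pre = np.empty((0, system.n_vars))
    post = grid[grid > t_c + 1e-12]
    if len(post):
        ts = np.concatenate(([t_c], post))
        act = _integrate_segments(
            lambda t, y: system.derivative(t, y, active=True), y_at_tc, ts, [], cfg)
        states = np.vstack([states_pre, act[1:]]) if len(states_pre) else act[1:]
        if t_c <= t0:
            states = np.vstack([y0[None, :], states]) if len(states) < len(grid) else states
    else:
        states = states_pre
    if states.shape[0] != len(grid):  # pragma: no cover - defensive
        raise IntegrationError("onset sampling bookkeeping error")
    _check_nonneg(system.units, system.var_labels, states, cfg.atol)
    prov = {"system": system.manifest(), "integrator": cfg.manifest(),
            "t0": float(t0), "t_end": float(t_end), "t_c": float(t_c)}
    return Trajectory(t0, cfg.dt_out, states, system.var_labels, prov)


def continue_coupled(system: CoupledSystem, state: Sequence[float], t_start: float,
                     t_end: float, cfg: IntegratorConfig | None = None) -> Trajectory:
    """Integrate a coupled pair with the coupling already active.

    Sweep protocols integrate the shared free-running leg once and then
    call this for each onset time, which is equivalent to
    :func:`integrate_with_onset` restricted to ``t >= t_c``.
    """
    cfg = cfg or IntegratorConfig()
    grid = _output_grid(t_start, t_end, cfg.dt_out)
    states = _integrate_segments(
        lambda t, y: system.derivative(t, y, active=True),
        np.asarray(state, float), grid, [], cfg)
    _check_nonneg(system.units, system.var_labels, states, cfg.atol)
    prov = {"system": system.manifest(), "integrator": cfg.manifest(),
            "t0": float(t_start), "t_end": float(t_end), "t_c": float(t_start)}
    return Trajectory(t_start, cfg.dt_out, states, system.var_labels, prov)


def apply_pulse(model: OscillatorModel, state: Sequence[float], pulse: PulseSpec,
                t_end: float, cfg: IntegratorConfig | None = None) -> Trajectory:
    """Kick one variable instantaneously, then continue the integration.

    ``pulse.time`` is both the moment of the kick and the start time of
    the returned trajectory; the first sample is the post-pulse state.
    """
    cfg = cfg or IntegratorConfig()
    if pulse.time is None:
        raise ValidationError("apply_pulse needs an absolute pulse time; "
                              "resolve phase-specified pulses first")
    j = model.var_index(pulse.variable)
    y = np.asarray(state, dtype=float).copy()
    if y.shape != (model.n_vars,):
        raise ValidationError("state dimension mismatch")
    y[j] += pulse.magnitude
    if model.units[j] == "uM" and y[j] < 0:
        raise ValidationError(
            f"pulse drives concentration {pulse.variable!r} negative ({y[j]:.4g})")
    traj = integrate(model, y, pulse.time, t_end, cfg)
    traj.provenance["pulse"] = pulse.manifest()
    return traj
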