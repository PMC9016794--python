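"""Sweep protocols: onset-time censuses, two-parameter synchronization
diagrams, hysteresis ramps, entrainment (Arnold-tongue) maps, and
pulse-switch maps.

The central object is the :class:`ModeCensus`: run a family of
trajectories (one per coupling-onset time, or one per initial
condition), fingerprint every run that settles on a periodic attractor,
cluster the fingerprints, and count the distinct modes.  Coexisting
synchronized regimes — multi-synchronization — show up as more than one
cluster at a single parameter point; each mode's basin fraction is the
share of runs that selected it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .engine import (IntegratorConfig, PulseSpec, Trajectory, apply_pulse,
                     continue_coupled, integrate)
from .errors import (InsufficientDataError, IntegrationError,
                     NotFingerprintableError, ValidationError)
from .models import CoupledSystem, ForcingSpec, OscillatorModel, make_forced
from .rhythm import (DEFAULTS, AttractorFingerprint, attractor_distance,
                     check_sync, classify_regime, estimate_period, fingerprint,
                     steady_fingerprint)

__all__ = ["ModeCensus", "SyncDiagram", "EntrainmentMap", "HysteresisResult",
           "SwitchMap", "onset_sweep", "initial_condition_census",
           "cluster_modes", "synchronization_diagram", "hysteresis_sweep",
           "arnold_map", "pulse_switch_map"]

log = logging.getLogger("multisync")

#: distance below which two fingerprints count as the same attractor
CLUSTER_THRESHOLD = 0.02

#: post-onset analysis window (h) used when no explicit discard is given
ANALYSIS_WINDOW = 300.0

_CLASSES = {0: "none", 1: "mono", 2: "bi", 3: "tri"}


def _classification(n_modes: int) -> str:
    return _CLASSES.get(n_modes, "higher")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_modes(fps: Sequence[AttractorFingerprint],
                  threshold: float = CLUSTER_THRESHOLD):
    """Single-linkage clustering of fingerprints under attractor distance.

    Returns ``(labels, representatives)``: integer labels per input (ids
    ordered by ascending representative period) and one representative
    fingerprint per cluster (the member with the median period).  Ties at
    exactly the threshold merge (conservative mode counting); the result
    is invariant under permutation of the inputs.
    """
    if len(fps) == 0:
        raise ValidationError("cannot cluster an empty fingerprint list")
    first = fps[0]
    for f in fps[1:]:
        if f.var_labels != first.var_labels or f.W != first.W:
            raise ValidationError("fingerprints cover different variable sets")
    n = len(fps)
    if n == 1:
        return np.zeros(1, dtype=int), [fps[0]]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = attractor_distance(fps[i], fps[j])
            dm[i, j] = dm[j, i] = min(d, 1e6)
    raw = fcluster(linkage(squareform(dm), method="single"),
                   t=threshold, criterion="distance")
    reps: dict[int, int] = {}
    for cid in np.unique(raw):
        members = np.where(raw == cid)[0]
        periods = np.array([fps[i].period for i in members])
        order = members[np.argsort(periods, kind="stable")]
        reps[cid] = int(order[(len(order) - 1) // 2])  # median period member
    def _order_key(cid):
        fp = fps[reps[cid]]
        # period at reporting precision, then amplitude: deterministic for
        # equal-period modes that differ only in amplitude
        T = float(np.nan_to_num(fp.period, nan=np.inf))
        return (round(T, 2), max(fp.amplitudes))

    order = sorted(reps, key=_order_key)
    remap = {cid: k for k, cid in enumerate(order)}
    labels = np.array([remap[c] for c in raw], dtype=int)
    representatives = [fps[reps[cid]] for cid in order]
    return labels, representatives


# ---------------------------------------------------------------------------
# censuses
# ---------------------------------------------------------------------------

@dataclass
class ModeCensus:
    """Distinct-attractor inventory from a sweep.

    ``assignments`` has one row per run (key column ``t_c`` or ``ic``),
    a ``status`` column (``locked``/``periodic`` runs carry a
    ``mode`` id; others are labeled ``unsynchronized``,
    ``complex_periodic``, ``aperiodic``, ``steady_state`` or ``failed``)
    and the measured period.  Basin fractions are over the runs assigned
    to a mode and sum to one when any run locked.
    """

    modes: list[AttractorFingerprint]
    counts: list[int]
    basin_fractions: list[float]
    assignments: pd.DataFrame
    threshold: float
    n_failed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def mode_periods(self) -> list[float]:
        return [round(fp.period, 2) for fp in self.modes]

    @property
    def classification(self) -> str:
        return _classification(self.n_modes)

    def summary(self) -> dict:
        return {
            "n_modes": self.n_modes,
            "classification": self.classification,
            "mode_periods_h": self.mode_periods,
            "counts": list(self.counts),
            "basin_fractions": [round(f, 6) for f in self.basin_fractions],
            "n_runs": int(len(self.assignments)),
            "n_failed": int(self.n_failed),
            "cluster_threshold": self.threshold,
        }


def _census_from_runs(keys, key_name, statuses, fps_by_key, periods, ratios,
                      threshold, n_failed, meta) -> ModeCensus:
    keyed = [k for k in keys if k in fps_by_key]
    mode_of_key: dict = {}
    if keyed:
        labels, reps = cluster_modes([fps_by_key[k] for k in keyed], threshold)
        mode_of_key = dict(zip(keyed, labels))
        counts = [int((labels == m).sum()) for m in range(len(reps))]
        fractions = [c / len(keyed) for c in counts]
    else:
        reps, counts, fractions = [], [], []
    rows = []
    for k in keys:
        rows.append({
            key_name: k,
            "status": statuses[k],
            "mode": int(mode_of_key[k]) if k in mode_of_key else -1,
            "period_h": periods.get(k, float("nan")),
            "ratio": ratios.get(k, ""),
        })
    assignments = pd.DataFrame(rows)
    return ModeCensus(modes=list(reps), counts=counts,
                      basin_fractions=fractions, assignments=assignments,
                      threshold=threshold, n_failed=n_failed, meta=meta)


def onset_sweep(system: CoupledSystem, t_c_start: float, t_c_end: float,
                dt_c: float, t_end: float,
                cfg: IntegratorConfig | None = None, *,
                discard: float | None = None,
                analysis_window: float = ANALYSIS_WINDOW,
                threshold: float = CLUSTER_THRESHOLD,
                tol_sync: float = DEFAULTS["tol_sync"],
                t0: float = 0.0,
                y0_clock: Sequence[float] | None = None,
                y0_cycle: Sequence[float] | None = None) -> ModeCensus:
    """Mode census over a grid of coupling-onset times.

    Both oscillators run free from ``t0``; one run per onset time ``t_c``
    on the inclusive grid switches the bidirectional coupling on at
    ``t_c`` and integrates to ``t_end``.  Because every run shares the
    same free-running prefix, that prefix is integrated once and each
    run continues from its own onset state.  Each run is sync-checked
    (clock readout vs cycle readout); locked runs are fingerprinted and
    clustered into modes.
    """
    cfg = cfg or IntegratorConfig()
    if not (dt_c > 0):
        raise ValidationError("dt_c must be > 0")
    if t_c_end < t_c_start:
        raise ValidationError("t_c_end must be >= t_c_start")
    n = int(round((t_c_end - t_c_start) / dt_c))
    t_cs = [round(t_c_start + i * dt_c, 9) for i in range(n + 1)]
    if t_cs[-1] > t_end:
        raise ValidationError("onset grid extends past t_end")

    y0c = list(y0_clock) if y0_clock is not None else list(system.clock.default_state)
    y0y = list(y0_cycle) if y0_cycle is not None else list(system.cycle.default_state)
    y0 = np.array(y0c + y0y, dtype=float)

    # shared free-running prefix, sampled exactly at every onset time
    from .engine import _integrate_segments  # reuse the segment driver

    prefix_grid = np.unique(np.concatenate(([t0], np.asarray(t_cs))))
    free_states = _integrate_segments(
        lambda t, y: system.derivative(t, y, active=False), y0, prefix_grid, [], cfg)
    state_at = {round(float(t), 9): s for t, s in zip(prefix_grid, free_states)}

    lab_A, lab_B = system.readout_labels()
    statuses, periods, ratios, fps = {}, {}, {}, {}
    n_failed = 0
    for t_c in t_cs:
        try:
            traj = continue_coupled(system, state_at[t_c], t_c, t_end, cfg)
            d = discard if discard is not None else max(0.0, (t_end - t_c) - analysis_window)
            res = check_sync(traj, lab_A, lab_B, discard=d, tol_sync=tol_sync)
            if res.locked:
                try:
                    fps[t_c] = fingerprint(traj, discard=d)
                    statuses[t_c] = "locked"
                    periods[t_c] = res.common_period
                    ratios[t_c] = f"{res.ratio[0]}:{res.ratio[1]}"
                    continue
                except (NotFingerprintableError, InsufficientDataError):
                    pass
            if not res.applicable:
                statuses[t_c] = "steady_state"
            else:
                statuses[t_c] = _failure_label(traj, lab_A, lab_B, d)
            if res.period_A is not None:
                periods[t_c] = res.period_A
        except IntegrationError as exc:
            log.warning("onset run t_c=%s failed: %s", t_c, exc)
            statuses[t_c] = "failed"
            n_failed += 1
    meta = {"protocol": "onset_sweep", "t_c_start": t_c_start,
            "t_c_end": t_c_end, "dt_c": dt_c, "t_end": t_end,
            "system": system.manifest(), "integrator": cfg.manifest()}
    return _census_from_runs(t_cs, "t_c", statuses, fps, periods, ratios,
                             threshold, n_failed, meta)


def _failure_label(traj: Trajectory, lab_A: str, lab_B: str, discard: float) -> str:
    """Sub-label an unsynchronized run: complex periodic vs aperiodic."""
    labels = set()
    for lab in (lab_A, lab_B):
        try:
            labels.add(classify_regime(traj, discard, lab))
        except InsufficientDataError:
            labels.add("aperiodic")
    if "aperiodic" in labels:
        return "aperiodic"
    if "complex_periodic" in labels:
        return "complex_periodic"
    if labels == {"steady_state"}:
        return "steady_state"
    return "unsynchronized"


def initial_condition_census(model: OscillatorModel,
                             initial_states: Sequence[Sequence[float]],
                             t_end: float,
                             cfg: IntegratorConfig | None = None, *,
                             discard: float | None = None,
                             analysis_window: float = ANALYSIS_WINDOW,
                             threshold: float = CLUSTER_THRESHOLD,
                             t0: float = 0.0) -> ModeCensus:
    """Attractor census of one model over a family of initial conditions.

    The basin-sampling analogue of :func:`onset_sweep` for a single
    (multi-rhythmic) oscillator: integrate from each initial state,
    classify, fingerprint the periodic runs and cluster them into modes.
    """
    cfg = cfg or IntegratorConfig()
    keys = list(range(len(initial_states)))
    statuses, periods, ratios, fps = {}, {}, {}, {}
    n_failed = 0
    d = discard if discard is not None else max(0.0, (t_end - t0) - analysis_window)
    for k, y0 in zip(keys, initial_states):
        try:
            traj = integrate(model, y0, t0, t_end, cfg)
            regime = classify_regime(traj, d)
            statuses[k] = regime
            if regime == "periodic":
                fps[k] = fingerprint(traj, discard=d)
                periods[k] = round(fps[k].period, 2)
        except IntegrationError as exc:
            log.warning("census run %d failed: %s", k, exc)
            statuses[k] = "failed"
            n_failed += 1
    meta = {"protocol": "initial_condition_census", "t_end": t_end,
            "model": model.manifest(), "integrator": cfg.manifest(),
            "initial_states": [list(map(float, s)) for s in initial_states]}
    return _census_from_runs(keys, "ic", statuses, fps, periods, ratios,
                             threshold, n_failed, meta)


# ---------------------------------------------------------------------------
# two-parameter synchronization diagram
# ---------------------------------------------------------------------------

@dataclass
class SyncDiagram:
    """Per-cell mode censuses over a (v_sw, K_ICdk1) grid.

    ``cells`` has one row per grid cell with the local mode count,
    classification and mode periods; ``surfaces`` assigns every cell mode
    to a globally consistent surface id (re-clustering of all cell
    representatives), the machine analogue of overlapping period
    surfaces.
    """

    v_sw_grid: np.ndarray
    K_grid: np.ndarray
    cells: pd.DataFrame
    surfaces: pd.DataFrame
    censuses: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def synchronization_diagram(clock: OscillatorModel, cycle: OscillatorModel,
                            v_sw_grid: Sequence[float],
                            K_grid: Sequence[float],
                            coupling_template, *,
                            t_c_start: float, t_c_end: float, n_onsets: int = 31,
                            t_end: float, cfg: IntegratorConfig | None = None,
                            threshold: float = CLUSTER_THRESHOLD,
                            analysis_window: float = ANALYSIS_WINDOW,
                            tol_sync: float = DEFAULTS["tol_sync"]) -> SyncDiagram:
    """Mono/bi/tri-synchronization diagram over a coupling-strength grid.

    For each cell, an onset sweep with a (usually reduced) onset grid
    yields the local census; cell representatives are then re-clustered
    jointly so mode identity (surface membership) is consistent across
    the diagram.
    """
    from dataclasses import replace as dc_replace

    from .models import CouplingSpec, make_coupled

    v_sw_grid = np.asarray(list(v_sw_grid), dtype=float)
    K_grid = np.asarray(list(K_grid), dtype=float)
    for g, name in ((v_sw_grid, "v_sw"), (K_grid, "K_ICdk1")):
        if len(g) == 0 or np.any(np.diff(g) <= 0):
            raise ValidationError(f"{name} grid must be strictly increasing")
    if np.any(K_grid <= 0):
        raise ValidationError("K_ICdk1 grid must be positive")
    dt_c = (t_c_end - t_c_start) / max(n_onsets - 1, 1)
    rows, censuses, rep_index = [], {}, []
    reps_all = []
    for v_sw in v_sw_grid:
        for K in K_grid:
            spec: CouplingSpec = dc_replace(coupling_template, v_sw=float(v_sw),
                                            K_ICdk1=float(K))
            system = make_coupled(clock, cycle, spec)
            try:
                census = onset_sweep(system, t_c_start, t_c_end, dt_c, t_end,
                                     cfg, threshold=threshold,
                                     analysis_window=analysis_window,
                                     tol_sync=tol_sync)
                censuses[(float(v_sw), float(K))] = census
                rows.append({"v_sw": v_sw, "K_ICdk1": K,
                             "n_modes": census.n_modes,
                             "classification": census.classification,
                             "mode_periods_h": ";".join(f"{p:.2f}" for p in census.mode_periods),
                             "n_failed": census.n_failed, "error": ""})
                for m, fp in enumerate(census.modes):
                    reps_all.append(fp)
                    rep_index.append((float(v_sw), float(K), m))
            except (IntegrationError, ValidationError) as exc:
                rows.append({"v_sw": v_sw, "K_ICdk1": K, "n_modes": -1,
                             "classification": "failed",
                             "mode_periods_h": "", "n_failed": -1,
                             "error": str(exc)})
    cells = pd.DataFrame(rows)
    if reps_all:
        labels, _ = cluster_modes(reps_all, threshold)
        surfaces = pd.DataFrame(
            [{"v_sw": v, "K_ICdk1": k, "cell_mode": m, "surface": int(s),
              "period_h": round(fp.period, 2)}
             for (v, k, m), s, fp in zip(rep_index, labels, reps_all)])
    else:
        surfaces = pd.DataFrame(
            columns=["v_sw", "K_ICdk1", "cell_mode", "surface", "period_h"])
    meta = {"protocol": "synchronization_diagram",
            "t_c_start": t_c_start, "t_c_end": t_c_end, "n_onsets": n_onsets,
            "t_end": t_end, "threshold": threshold}
    return SyncDiagram(v_sw_grid, K_grid, cells, surfaces, censuses, meta)


# ---------------------------------------------------------------------------
# hysteresis
# ---------------------------------------------------------------------------

@dataclass
class HysteresisResult:
    """Forward/backward parameter-ramp fingerprints and their disagreement."""

    parameter: str
    grid: np.ndarray
    forward: list[AttractorFingerprint]
    backward: list[AttractorFingerprint]
    distances: np.ndarray
    disagreement: np.ndarray  # boolean mask over the grid
    windows: list[tuple[float, float]]
    meta: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.grid):
            rows.append({
                self.parameter: g,
                "forward_regime": self.forward[i].regime,
                "forward_period_h": self.forward[i].period,
                "forward_amp": max(self.forward[i].amplitudes),
                "backward_regime": self.backward[i].regime,
                "backward_period_h": self.backward[i].period,
                "backward_amp": max(self.backward[i].amplitudes),
                "distance": self.distances[i],
                "disagree": bool(self.disagreement[i]),
            })
        return pd.DataFrame(rows)


def hysteresis_sweep(model: OscillatorModel, parameter: str, lo: float,
                     hi: float, n_steps: int, settle: float,
                     cfg: IntegratorConfig | None = None, *,
                     analysis_window: float = ANALYSIS_WINDOW,
                     threshold: float = CLUSTER_THRESHOLD,
                     y0_forward: Sequence[float] | None = None,
                     y0_backward: Sequence[float] | None = None) -> HysteresisResult:
    """Ramp a parameter up then down, carrying the state between steps.

    At every step the model runs for ``settle`` hours from the previous
    step's final state and is fingerprinted on the last
    ``analysis_window`` hours (loss of oscillation yields a steady-state
    fingerprint, not an error).  The backward branch starts from
    ``y0_backward`` if given, otherwise from the forward branch's final
    state.  The disagreement window is where forward and backward
    fingerprints differ by more than the cluster threshold — the
    hallmark of coexisting attractors.
    """
    cfg = cfg or IntegratorConfig()
    if n_steps < 3:
        raise ValidationError("n_steps must be >= 3")
    if parameter not in model.params:
        raise ValidationError(f"unknown parameter {parameter!r}")
    grid = np.linspace(lo, hi, n_steps)
    discard = max(0.0, settle - analysis_window)

    def branch(values, y_start):
        fps, y = [], np.asarray(y_start, dtype=float)
        for val in values:
            m = model.with_params(**{parameter: float(val)})
            traj = integrate(m, y, 0.0, settle, cfg)
            y = traj.data[-1, : model.n_vars]
            try:
                fps.append(fingerprint(traj, discard=discard))
            except (NotFingerprintableError, InsufficientDataError):
                fps.append(steady_fingerprint(traj, discard=discard))
        return fps, y

    y0f = y0_forward if y0_forward is not None else model.default_state
    fwd, y_end = branch(grid, y0f)
    y0b = y0_backward if y0_backward is not None else y_end
    bwd_rev, _ = branch(grid[::-1], y0b)
    bwd = bwd_rev[::-1]
    distances = np.array([attractor_distance(a, b) for a, b in zip(fwd, bwd)])
    disagree = distances > threshold
    windows = []
    i = 0
    while i < len(grid):
        if disagree[i]:
            j = i
            while j + 1 < len(grid) and disagree[j + 1]:
                j += 1
            windows.append((float(grid[i]), float(grid[j])))
            i = j + 1
        else:
            i += 1
    meta = {"protocol": "hysteresis_sweep", "parameter": parameter,
            "lo": lo, "hi": hi, "n_steps": n_steps, "settle": settle,
            "model": model.manifest()}
    return HysteresisResult(parameter, grid, fwd, bwd, distances, disagree,
                            windows, meta)


# ---------------------------------------------------------------------------
# entrainment maps
# ---------------------------------------------------------------------------

@dataclass
class EntrainmentMap:
    """p:q entrainment verdicts over a (forcing period, amplitude) grid."""

    period_grid: np.ndarray
    amplitude_grid: np.ndarray
    runs: pd.DataFrame       # one row per (T_f, amp, phase)
    cells: pd.DataFrame      # one row per (T_f, amp): consensus verdict
    overlap: pd.DataFrame    # cells whose verdict differs across phases
    meta: dict = field(default_factory=dict)

    def tongue_widths(self, p: int = 1, q: int = 1) -> pd.DataFrame:
        """Locked-cell count per amplitude for the p:q tongue."""
        tag = f"{p}:{q}"
        rows = []
        for amp in self.amplitude_grid:
            sub = self.cells[(self.cells["amplitude"] == amp)
                             & (self.cells["ratio"] == tag)
                             & self.cells["locked"]]
            rows.append({"amplitude": amp, "n_locked": int(len(sub))})
        return pd.DataFrame(rows)


def arnold_map(model: OscillatorModel, target: str,
               period_grid: Sequence[float], amplitude_grid: Sequence[float],
               n_phases: int = 1, *, kind: str = "sinusoid",
               response_var: str | None = None,
               t_end: float = 1200.0, discard: float = 800.0,
               cfg: IntegratorConfig | None = None,
               tol_sync: float = DEFAULTS["tol_sync"],
               cv_lock: float = DEFAULTS["cv_per"]) -> EntrainmentMap:
    """p:q entrainment map of a periodically forced oscillator.

    For every (forcing period, amplitude) cell the forced model runs from
    ``n_phases`` initial states spread over one free-running cycle.  A
    run is locked p:q when its response period satisfies ``|p*T_resp -
    q*T_f| < tol_sync * q*T_f`` with a regular rhythm (interval CV below
    ``cv_lock``).  Cells where runs from different phases lock
    differently are flagged as overlap — coexisting entrainment modes.
    """
    cfg = cfg or IntegratorConfig()
    if n_phases < 1:
        raise ValidationError("n_phases must be >= 1")
    period_grid = np.asarray(list(period_grid), dtype=float)
    amplitude_grid = np.asarray(list(amplitude_grid), dtype=float)
    if response_var is None:
        response_var = next(iter(model.output_ports.values()), model.var_labels[0])

    # free-running reference cycle: phases for the initial conditions
    free = integrate(model, model.default_state, 0.0,
                     30.0 * (model.nominal_period or 24.0), cfg)
    d_free = free.t_end - free.t0 - 12.0 * (model.nominal_period or 24.0)
    fp_free = fingerprint(free, discard=d_free, ref_var=response_var)
    T_free = fp_free.period
    t_anchor = _anchor_time(free, response_var, d_free)
    tt = free.t
    phase_states = []
    for k in range(n_phases):
        tk = t_anchor + (k / n_phases) * T_free
        phase_states.append(np.array([np.interp(tk, tt, free.data[:, j])
                                      for j in range(model.n_vars)]))

    run_rows = []
    for T_f in period_grid:
        for amp in amplitude_grid:
            for k, y0 in enumerate(phase_states):
                verdict = _entrain_verdict(model, target, kind, T_f, amp, y0,
                                           response_var, t_end, discard, cfg,
                                           tol_sync, cv_lock)
                verdict.update({"T_f": T_f, "amplitude": amp, "phase_idx": k})
                run_rows.append(verdict)
    runs = pd.DataFrame(run_rows)
    cell_rows, overlap_rows = [], []
    for T_f in period_grid:
        for amp in amplitude_grid:
            sub = runs[(runs["T_f"] == T_f) & (runs["amplitude"] == amp)]
            verdicts = set(zip(sub["locked"], sub["ratio"]))
            locked = bool(sub["locked"].all())
            ratio = sub["ratio"].iloc[0] if locked and len(verdicts) == 1 else ""
            cell_rows.append({"T_f": T_f, "amplitude": amp,
                              "locked": locked and len(verdicts) == 1,
                              "ratio": ratio,
                              "period_h": sub["period_h"].iloc[0]})
            if len(verdicts) > 1:
                overlap_rows.append({"T_f": T_f, "amplitude": amp,
                                     "verdicts": sorted(map(str, verdicts))})
    meta = {"protocol": "arnold_map", "target": target, "kind": kind,
            "free_period_h": T_free, "t_end": t_end, "discard": discard,
            "model": model.manifest()}
    return EntrainmentMap(period_grid, amplitude_grid, runs,
                          pd.DataFrame(cell_rows), pd.DataFrame(overlap_rows),
                          meta)


def _entrain_verdict(model, target, kind, T_f, amp, y0, response_var,
                     t_end, discard, cfg, tol_sync, cv_lock) -> dict:
    out = {"locked": False, "ratio": "", "period_h": float("nan")}
    if amp > 0:
        forced = make_forced(model, ForcingSpec(target=target, kind=kind,
                                                period=float(T_f),
                                                amplitude=float(amp)))
    else:
        forced = model
    try:
        traj = integrate(forced, y0, 0.0, t_end, cfg)
        est = estimate_period(traj, response_var, discard=discard)
    except IntegrationError:
        out["ratio"] = "failed"
        return out
    except Exception:
        return out
    out["period_h"] = est.period
    if est.cv >= cv_lock:
        return out
    from math import gcd

    best = None
    for p in range(1, 5):
        for q in range(1, 5):
            if gcd(p, q) != 1:
                continue
            err = abs(p * est.period_exact - q * T_f) / (q * T_f)
            if best is None or err < best[0]:
                best = (err, p, q)
    err, p, q = best
    if err < tol_sync:
        out["locked"] = True
        out["ratio"] = f"{p}:{q}"
    return out


def _anchor_time(traj: Trajectory, var: str, discard: float) -> float:
    t = traj.t
    x = traj[var]
    mask = t >= traj.t0 + discard
    ts, xs = t[mask], x[mask]
    level = 0.5 * (xs.max() + xs.min())
    up = np.where((xs[:-1] <= level) & (xs[1:] > level))[0]
    if len(up) == 0:
        raise NotFingerprintableError("no anchor crossing found")
    i = up[0]
    frac = (level - xs[i]) / (xs[i + 1] - xs[i])
    return float(ts[i] + frac * (ts[1] - ts[0]))


# ---------------------------------------------------------------------------
# pulse-switch maps
# ---------------------------------------------------------------------------

@dataclass
class SwitchMap:
    """Destination attractor per (pulse phase, pulse magnitude)."""

    phase_grid: np.ndarray
    magnitude_grid: np.ndarray
    table: pd.DataFrame
    source_mode: int
    meta: dict = field(default_factory=dict)


def pulse_switch_map(model: OscillatorModel, source_state: Sequence[float],
                     pulse_var: str, phase_grid: Sequence[float],
                     magnitude_grid: Sequence[float],
                     modes: Sequence[AttractorFingerprint], *,
                     settle: float = 400.0, t_post: float = 600.0,
                     analysis_window: float = ANALYSIS_WINDOW,
                     threshold: float = CLUSTER_THRESHOLD,
                     ref_var: str | None = None,
                     cfg: IntegratorConfig | None = None) -> SwitchMap:
    """Map pulse-induced transitions between coexisting limit cycles.

    The model first settles from ``source_state`` onto its attractor;
    pulses of each magnitude are applied at each phase of that cycle
    (phase 0 = the fingerprint anchor), the post-pulse trajectory is
    fingerprinted and assigned to the nearest of the reference ``modes``.
    The zero-magnitude row maps every phase back to the source mode by
    construction.
    """
    cfg = cfg or IntegratorConfig()
    if len(modes) < 2:
        raise ValidationError("need >= 2 reference modes (coexisting attractors)")
    phase_grid = np.asarray(list(phase_grid), dtype=float)
    magnitude_grid = np.asarray(list(magnitude_grid), dtype=float)
    d = max(0.0, settle - analysis_window)
    base = integrate(model, source_state, 0.0, settle, cfg)
    fp_src = fingerprint(base, discard=d, ref_var=ref_var)
    source_mode = _nearest_mode(fp_src, modes, threshold)
    T = fp_src.period
    t_anchor = _anchor_time(base, fp_src.ref_var, d)
    tt = base.t
    rows = []
    for phase in phase_grid:
        t_p = t_anchor + float(phase) * T
        state = np.array([np.interp(t_p, tt, base.data[:, j])
                          for j in range(model.n_vars)])
        for mag in magnitude_grid:
            try:
                traj = apply_pulse(model, state,
                                   PulseSpec(variable=pulse_var,
                                             magnitude=float(mag), time=t_p),
                                   t_p + t_post, cfg)
                fp = fingerprint(traj, discard=max(0.0, t_post - analysis_window))
                dest = _nearest_mode(fp, modes, threshold)
                rows.append({"phase": phase, "magnitude": mag,
                             "dest_mode": dest, "period_h": round(fp.period, 2)})
            except (IntegrationError, ValidationError,
                    NotFingerprintableError, InsufficientDataError) as exc:
                rows.append({"phase": phase, "magnitude": mag,
                             "dest_mode": -1, "period_h": float("nan")})
                log.warning("pulse cell (%.3f, %.3f) invalid: %s", phase, mag, exc)
    meta = {"protocol": "pulse_switch_map", "pulse_var": pulse_var,
            "settle": settle, "t_post": t_post, "model": model.manifest()}
    return SwitchMap(phase_grid, magnitude_grid, pd.DataFrame(rows),
                     source_mode, meta)


def _nearest_mode(fp: AttractorFingerprint,
                  modes: Sequence[AttractorFingerprint],
                  threshold: float) -> int:
    dists = [attractor_distance(fp, m) for m in modes]
    i = int(np.argmin(dists))
    return i if dists[i] <= threshold else -1
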