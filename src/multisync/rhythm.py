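"""Period estimation, regime classification, attractor fingerprints, and
synchronization verdicts.

The unit of attractor identity is the :class:`AttractorFingerprint`:
period, per-variable amplitudes, and a min-max-normalised one-cycle
waveform resampled on a fixed grid.  Two fingerprints are compared by
:func:`attractor_distance`, which is what the census machinery in
:mod:`multisync.scans` clusters on.

Periods are measured from inter-peak intervals: local maxima of the
chosen variable after a transient-discard window, with quadratic
sub-sample refinement of each peak time.  Aperiodicity is diagnosed by
elimination (flat -> steady state; regular peaks -> periodic; a repeating
2-8 cycle pattern of intervals/heights -> complex periodic; anything
else -> aperiodic) rather than by Lyapunov exponents, which is cheap and
sufficient for census purposes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .engine import Trajectory
from .errors import (InsufficientDataError, NoOscillationError,
                     NotFingerprintableError, SteadyStateError,
                     ValidationError)

__all__ = ["PeriodEstimate", "AttractorFingerprint", "SyncResult",
           "estimate_period", "classify_regime", "fingerprint",
           "attractor_distance", "check_sync",
           "REGIMES", "DEFAULTS"]

REGIMES = ("steady_state", "periodic", "complex_periodic", "aperiodic")

#: Documented analysis defaults.  The period is reported to 0.01 h.
DEFAULTS = dict(
    tol_sync=1e-2,    # relative tolerance for p:q locking
    cv_per=1e-3,      # max CV of inter-peak intervals for "periodic"
    tol_amp=1e-2,     # max relative spread of peak heights for "periodic"
    tol_flat=1e-5,    # absolute range below which a signal is flat
    W=256,            # waveform resampling grid
    max_pattern=8,    # longest repeating pattern called "complex periodic"
    prominence_frac=0.05,  # peak prominence as a fraction of signal range
)

PERIOD_DECIMALS = 2


@dataclass(frozen=True)
class PeriodEstimate:
    """Mean inter-peak interval of one variable, reported to 0.01 h."""

    period: float        # h, rounded to 0.01
    sd: float            # SD of successive inter-peak intervals, h
    n_cycles: int
    variable: str
    period_exact: float  # unrounded mean, for downstream arithmetic

    @property
    def cv(self) -> float:
        return self.sd / self.period_exact


@dataclass(frozen=True)
class AttractorFingerprint:
    """Period + amplitudes + normalised one-cycle waveform + regime label."""

    period: float                 # h (NaN for non-periodic regimes)
    amplitudes: tuple[float, ...]  # per variable, max - min over one cycle
    waveform: np.ndarray          # (n_vars, W), each row min-max normalised
    regime: str
    var_labels: tuple[str, ...]
    ref_var: str = ""

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown regime {self.regime!r}")
        if self.waveform.shape[0] != len(self.var_labels):
            raise ValidationError("waveform/var_labels mismatch")

    @property
    def W(self) -> int:
        return self.waveform.shape[1]

    def manifest(self) -> dict:
        return {
            "period": None if math.isnan(self.period) else round(float(self.period), 4),
            "amplitudes": {v: round(float(a), 6)
                           for v, a in zip(self.var_labels, self.amplitudes)},
            "regime": self.regime,
            "ref_var": self.ref_var,
            "W": int(self.W),
        }


@dataclass(frozen=True)
class SyncResult:
    """p:q locking verdict for two variables of one trajectory.

    ``ratio = (p, q)`` means p cycles of variable A per q cycles of
    variable B; the lock condition is ``|p*T_A - q*T_B| < tol_sync *
    q*T_B`` together with a matching peak-count ratio over the analysis
    window.  ``applicable`` is False when either variable does not
    oscillate (e.g. one oscillator suppressed), which is a flagged
    outcome, not an error.
    """

    locked: bool
    ratio: tuple[int, int] | None
    common_period: float | None
    period_A: float | None
    period_B: float | None
    applicable: bool = True


# ---------------------------------------------------------------------------
# peak machinery
# ---------------------------------------------------------------------------

def _analysis_window(traj: Trajectory, variable: str, discard: float):
    x = traj[variable]
    t = traj.t
    mask = t >= traj.t0 + discard
    if mask.sum() < 8:
        raise InsufficientDataError("analysis window shorter than 8 samples")
    return t[mask], x[mask]


def _refined_peaks(t: np.ndarray, x: np.ndarray, prominence_frac: float):
    """Peak times and heights with quadratic sub-sample refinement."""
    rng = x.max() - x.min()
    idx, _ = find_peaks(x, prominence=prominence_frac * rng)
    idx = idx[(idx > 0) & (idx < len(x) - 1)]
    if len(idx) == 0:
        return np.array([]), np.array([])
    dt = t[1] - t[0]
    ym1, y0, yp1 = x[idx - 1], x[idx], x[idx + 1]
    denom = ym1 - 2.0 * y0 + yp1
    offset = np.where(np.abs(denom) > 0, 0.5 * (ym1 - yp1) / np.where(denom == 0, 1, denom), 0.0)
    times = t[idx] + offset * dt
    heights = y0 - 0.25 * (ym1 - yp1) * offset
    return times, heights


def estimate_period(traj: Trajectory, variable: str, discard: float = 0.0,
                    prominence_frac: float = DEFAULTS["prominence_frac"],
                    tol_flat: float = DEFAULTS["tol_flat"]) -> PeriodEstimate:
    """Mean inter-peak interval of ``variable`` after the transient window."""
    t, x = _analysis_window(traj, variable, discard)
    if x.max() - x.min() < tol_flat:
        raise SteadyStateError(
            f"{variable}: signal range {x.max() - x.min():.2e} below tol_flat")
    times, _ = _refined_peaks(t, x, prominence_frac)
    if len(times) < 3:
        raise NoOscillationError(
            f"{variable}: only {len(times)} peaks after discard")
    iv = np.diff(times)
    mean = float(iv.mean())
    return PeriodEstimate(
        period=round(mean, PERIOD_DECIMALS),
        sd=float(iv.std(ddof=0)),
        n_cycles=len(iv),
        variable=variable,
        period_exact=mean,
    )


def classify_regime(traj: Trajectory, discard: float = 0.0,
                    variable: str | None = None, *,
                    tol_flat: float = DEFAULTS["tol_flat"],
                    cv_per: float = DEFAULTS["cv_per"],
                    tol_amp: float = DEFAULTS["tol_amp"],
                    max_pattern: int = DEFAULTS["max_pattern"],
                    prominence_frac: float = DEFAULTS["prominence_frac"]) -> str:
    """Label the post-transient dynamics of one variable.

    steady_state: flat within ``tol_flat``.  periodic: inter-peak
    intervals with CV < ``cv_per`` and peak heights within ``tol_amp``
    of each other (relative to the signal range).  complex_periodic: the
    interval/height sequence repeats with a pattern of 2 to
    ``max_pattern`` cycles.  aperiodic: everything else.
    """
    if variable is None:
        variable = _widest_variable(traj, discard)
    t, x = _analysis_window(traj, variable, discard)
    rng = x.max() - x.min()
    if rng < tol_flat:
        return "steady_state"
    times, heights = _refined_peaks(t, x, prominence_frac)
    if len(times) < 3:
        return "steady_state"
    iv = np.diff(times)
    if len(iv) < 10:
        raise InsufficientDataError(
            f"{variable}: only {len(iv)} intervals; need >= 10 cycles post-discard")
    if _pattern_fits(iv, heights[1:], 1, cv_per, tol_amp, rng):
        return "periodic"
    for L in range(2, max_pattern + 1):
        if len(iv) >= 2 * L + 2 and _pattern_fits(iv, heights[1:], L, cv_per, tol_amp, rng):
            return "complex_periodic"
    return "aperiodic"


def _pattern_fits(iv: np.ndarray, heights: np.ndarray, L: int,
                  cv_per: float, tol_amp: float, rng: float) -> bool:
    """Do intervals and peak heights repeat with pattern length L?"""
    for r in range(L):
        sub = iv[r::L]
        if len(sub) < 2:
            return False
        if sub.std(ddof=0) / iv.mean() >= cv_per * L:
            return False
        hsub = heights[r::L]
        if (hsub.max() - hsub.min()) >= tol_amp * rng:
            return False
    return True


def _widest_variable(traj: Trajectory, discard: float) -> str:
    t = traj.t
    mask = t >= traj.t0 + discard
    sub = traj.data[mask]
    ranges = sub.max(axis=0) - sub.min(axis=0)
    return traj.var_labels[int(np.argmax(ranges))]


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

def fingerprint(traj: Trajectory, discard: float = 0.0,
                ref_var: str | None = None, W: int = DEFAULTS["W"],
                **classify_kw) -> AttractorFingerprint:
    """One-cycle waveform fingerprint of a periodic trajectory.

    The cycle is cut at the first upward crossing of the reference
    variable's half-range level after the discard window and resampled to
    ``W`` points per variable; amplitudes (max - min) are measured on the
    final full cycle.
    """
    if ref_var is None:
        ref_var = _widest_variable(traj, discard)
    regime = classify_regime(traj, discard, ref_var, **classify_kw)
    if regime != "periodic":
        raise NotFingerprintableError(f"regime is {regime!r}, not periodic")
    est = estimate_period(traj, ref_var, discard)
    T = est.period_exact
    t, x = _analysis_window(traj, ref_var, discard)
    level = 0.5 * (x.max() + x.min())
    up = np.where((x[:-1] <= level) & (x[1:] > level))[0]
    if len(up) == 0:
        raise NotFingerprintableError("no anchor crossing found")
    i = up[0]
    # linear sub-sample crossing time
    frac = (level - x[i]) / (x[i + 1] - x[i])
    t_anchor = t[i] + frac * (t[1] - t[0])
    if t_anchor + T > t[-1]:
        raise InsufficientDataError("no full cycle after the anchor")
    grid = t_anchor + T * np.arange(W) / W
    tt = traj.t
    wave = np.empty((len(traj.var_labels), W))
    amps = []
    t_last0 = t[-1] - T
    for j, lab in enumerate(traj.var_labels):
        col = traj.data[:, j]
        wave[j] = np.interp(grid, tt, col)
        lo, hi = wave[j].min(), wave[j].max()
        if hi - lo > 1e-12:
            wave[j] = (wave[j] - lo) / (hi - lo)
        else:
            wave[j] = np.full(W, 0.5)
        cyc = col[(tt >= t_last0) & (tt <= t[-1] + 1e-12)]
        amps.append(float(cyc.max() - cyc.min()))
    return AttractorFingerprint(
        period=T, amplitudes=tuple(amps), waveform=wave, regime="periodic",
        var_labels=traj.var_labels, ref_var=ref_var)


def steady_fingerprint(traj: Trajectory, discard: float = 0.0,
                       W: int = DEFAULTS["W"]) -> AttractorFingerprint:
    """Degenerate fingerprint for a trajectory that settled to a point."""
    t = traj.t
    sub = traj.data[t >= traj.t0 + discard]
    amps = tuple(float(a) for a in (sub.max(axis=0) - sub.min(axis=0)))
    return AttractorFingerprint(
        period=float("nan"), amplitudes=amps,
        waveform=np.full((len(traj.var_labels), W), 0.5),
        regime="steady_state", var_labels=traj.var_labels)


_AMP_FLOOR = 1e-6


def attractor_distance(a: AttractorFingerprint, b: AttractorFingerprint) -> float:
    """Dissimilarity of two attractor fingerprints.

    The maximum of three non-negative terms: relative period difference,
    the smallest root-mean-square difference of the normalised waveforms
    over all cyclic shifts, and the largest relative per-variable
    amplitude difference.  Symmetric, zero on identical inputs, and
    invariant to cyclic waveform shifts within resampling error.
    Fingerprints of unlike regimes (periodic vs steady) are infinitely
    far apart.
    """
    if a.var_labels != b.var_labels:
        raise ValidationError("fingerprints cover different variable sets")
    if a.W != b.W:
        raise ValidationError("fingerprints use different waveform grids")
    steady_a = a.regime == "steady_state"
    steady_b = b.regime == "steady_state"
    damp = max(
        abs(x - y) / max(x, y, _AMP_FLOOR)
        for x, y in zip(a.amplitudes, b.amplitudes)
    )
    if steady_a and steady_b:
        return damp
    if steady_a or steady_b:
        return float("inf")
    dT = abs(a.period - b.period) / min(a.period, b.period)
    dwave = _min_shift_rms(a.waveform, b.waveform)
    return max(dT, dwave, damp)


def _min_shift_rms(wa: np.ndarray, wb: np.ndarray) -> float:
    """Min over cyclic shifts of the RMS difference, via FFT correlation."""
    n_vars, W = wa.shape
    fa = np.fft.rfft(wa, axis=1)
    fb = np.fft.rfft(wb, axis=1)
    # sum over variables of the circular cross-correlation at every shift
    corr = np.fft.irfft(fa * np.conj(fb), n=W, axis=1).sum(axis=0)
    sq = (wa ** 2).sum() + (wb ** 2).sum() - 2.0 * corr
    sq = np.maximum(sq, 0.0)
    return float(np.sqrt(sq.min() / (n_vars * W)))


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------

_RATIOS = tuple((p, q) for p in range(1, 5) for q in range(1, 5)
                if math.gcd(p, q) == 1)


def check_sync(traj: Trajectory, var_A: str, var_B: str, discard: float = 0.0,
               tol_sync: float = DEFAULTS["tol_sync"]) -> SyncResult:
    """p:q locking verdict between two variables of one trajectory."""
    ests = []
    for var in (var_A, var_B):
        try:
            ests.append(estimate_period(traj, var, discard))
        except (SteadyStateError, NoOscillationError):
            return SyncResult(locked=False, ratio=None, common_period=None,
                              period_A=None, period_B=None, applicable=False)
    TA, TB = ests[0].period_exact, ests[1].period_exact
    nA, nB = ests[0].n_cycles, ests[1].n_cycles
    best = None
    for p, q in _RATIOS:
        err = abs(p * TA - q * TB) / (q * TB)
        if best is None or err < best[0]:
            best = (err, p, q)
    err, p, q = best
    locked = err < tol_sync and abs(nA * q - nB * p) <= (p + q)
    return SyncResult(
        locked=locked,
        ratio=(p, q) if locked else None,
        common_period=round(p * TA, PERIOD_DECIMALS) if locked else None,
        period_A=ests[0].period,
        period_B=ests[1].period,
    )
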