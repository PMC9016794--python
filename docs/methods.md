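# Methods

## Problem and approach

Two cellular oscillators — the circadian clock (free-running period
~24 h) and the cell cycle (here 19.1 h) — can be coupled in both
directions: the clock induces the kinase Wee1 (which inhibits Cdk1),
and Cdk1 represses clock gene transcription during mitosis.  A
bidirectionally coupled pair usually synchronizes to a single common
period, but at some coupling strengths two or three *distinct*
synchronized regimes coexist, each with its own period, waveform and
basin of attraction ("multi-synchronization").  This package provides
the numerical instruments for detecting and mapping that coexistence:

1. simulate the coupled pair deterministically,
2. select among coexisting attractors by varying the **coupling onset
   time** `t_c` (each onset time is a different initial condition for
   the coupled flow, while the two free-running oscillators are on
   their own limit cycles),
3. reduce each run to an **attractor fingerprint** and cluster the
   fingerprints into modes,
4. count the modes per parameter point (mono/bi/tri/none), and
5. cross-check the machinery with the generic multi-rhythmicity
   instruments: hysteresis ramps, pulse-induced switching, and p:q
   entrainment (Arnold-tongue) maps.

## Models

### Analytic normal form (the oracle)

A planar system with radial dynamics
`dr/dt = -k r * prod_i (r^2 - rho_i^2)` and angular dynamics
`dtheta/dt = omega0 + beta r^2`.  With an odd number of strictly
increasing radii, circles at `rho_1, rho_3, ...` are stable limit
cycles and the interleaved ones unstable; the cycle at radius `rho`
has period `2*pi/(omega0 + beta rho^2)` **exactly**, and basins of
attraction follow from the sign of the radial polynomial.  Every
census, clustering, hysteresis and pulse protocol in the package is
validated against these closed forms.  Defaults: `k = 1e-2` and radii
kept at or below ~3–4, which bounds the stiffness of the radial
polynomial.  The hysteresis variant replaces the radial polynomial by
`-k r (r^2-1)((r^2-c)^2 - mu)`: for `mu` in `(0, (c-1)^2]` the unit
cycle coexists with an outer cycle of radius `sqrt(c + sqrt(mu))`, so
the bistable window and branch amplitudes are known in closed form.

### Clock stand-in (3 variables)

A negative-transcriptional-feedback loop: clock mRNA `M` is
synthesized under Hill repression (exponent `n = 6`) by the nuclear
repressor `I` and multiplied by the mitotic-repression input port `R`
(neutral value 1); protein `P` is translated from `M`; `I` derives
from `P`; all three degradations are Michaelian (which permits limit
cycles at moderate Hill exponents).  `P` is the clock readout, a
BMAL1-like proxy that drives Wee1 induction when coupled.  `n = 6`
rather than the minimal 4 because the n = 4 cycle is weakly attracting
(inter-peak-interval CV still ~1e-3 after 800 h), which would blur the
periodic/complex classification; at n = 6 transients die within a few
hundred hours.

All rates are divided by the time scale `tau`, so the period is exactly
linear in `tau`.  The base period at `tau = 1` was measured once
(27.4693739 h, LSODA at rtol 1e-10) and `tau_ref = 24.0/27.4693739` is
frozen in `_calibration.py`; no iterative tuning is needed.  A
construction-time self-check (memoised per parameter set) re-verifies
sustained oscillation with the advertised period.

### Cell-cycle stand-in (4 variables)

A relaxation-type Cdk1 oscillator in the spirit of minimal mitotic
cascade models: cyclin `C` accumulates at a constant rate and is
degraded when the APC-like activator `X` is on; Cdk1-like activity `A`
(total pool 1 µM) is activated by cyclin through a Michaelian step and
inactivated at a rate increased by the Wee1-like inhibitor `W`; `X` is
activated by `A`; `W` has basal synthesis 0.05 µM/h plus the
`wee1_induction` input port (neutral 0) and first-order decay.
Michaelian thresholds use `K = 0.05` (fraction units): sharper
thresholds (0.005) give the same qualitative relaxation oscillation at
roughly ten times the integration cost.  The global factor `eps`
divides all rates; the base period at `eps = 1` is 9.8644510, and
`eps_ref = 19.1/9.8644510` fixes the 19.1 h free-running period.

### Bidirectional coupling

For `t >= t_c` the cycle's Wee1 port receives
`u = v_sw * S^h_w / (K_w^h_w + S^h_w)` with `S` the clock readout, and
the clock's repression port receives
`R = K_ICdk1^g_r / (K_ICdk1^g_r + A^g_r)` with `A` the Cdk1-like
readout; `v_sw = 0` together with `K_ICdk1 -> inf` recovers the
uncoupled pair exactly.  Defaults `h_w = 4` (switch-like induction),
`g_r = 2` (graded repression), `K_w = 0.4` µM (mid-range of the clock
readout's swing).  Cdk1 repression applies to clock mRNA synthesis
only; which clock gene is repressed and the functional form of mitotic
repression are modelling choices, exposed in the configuration.  `u`
is interpreted in the cycle model's internal rate units (i.e. it is
divided by `eps` along with every other rate).

The shipped strong-coupling configuration `v_sw = 3.0` µM/h,
`K_ICdk1 = 1.5` µM locks every probed onset time into the same 1:1
mode (common period 23.12 h, between the two free-running periods);
weak mutual repression (`K_ICdk1` ~ 0.3) produces synchronization
failure with complex-periodic or aperiodic dynamics.  The plugin
registry (`multisync.models.registry`) accepts externally defined
oscillators — e.g. full mechanistic clock and cell-cycle models —
which then run through every protocol unchanged.

## Numerics

* **Integrator.**  LSODA (automatic Adams/BDF switching, stiff-capable)
  via `scipy.integrate.odeint`, wrapped by a segment driver that stops
  and restarts the solver at every discontinuity (coupling onset,
  pulses, square-wave forcing edges) instead of presenting the solver
  with a discontinuous right-hand side.  Defaults rtol 1e-8,
  atol 1e-10, output step 0.05 h.  Halving the tolerances moves
  reported periods by less than the 0.01 h reporting precision.
* **Non-negativity.**  Concentration variables are never clipped; a
  value below −10·atol aborts the run with an error.
* **Period estimation.**  Local maxima (prominence ≥ 5% of the signal
  range) after a transient-discard window, with quadratic sub-sample
  refinement of peak times and heights; the period is the mean
  inter-peak interval, reported to 0.01 h.
* **Regime labels.**  Flat (range < 1e-5) → steady state; interval
  CV < 1e-3 with peak heights within 1% of the range → periodic; a
  repeating pattern of 2–8 cycles in intervals/heights → complex
  periodic; otherwise aperiodic.  Aperiodicity is diagnosed by
  elimination, not by Lyapunov exponents — cheaper, and sufficient for
  counting modes.
* **Fingerprints.**  One cycle cut at the first upward half-range
  crossing of the reference variable after the discard window,
  resampled to W = 256 points per variable and min–max normalised;
  amplitudes (max − min per variable) from the final full cycle.
* **Distance.**  `d = max(relative period gap, min-over-cyclic-shifts
  RMS of normalised waveforms, max relative amplitude gap)`.  The
  amplitude term is required: concentric cycles of a shear-free normal
  form share period *and* normalised waveform and differ only in
  amplitude.  Steady-state fingerprints are at infinite distance from
  periodic ones.
* **Clustering.**  Single linkage under this distance with threshold
  0.02 (same attractor reached from different starts: d < 0.005;
  distinct synchronized modes in practice differ by ≥ 2% in period).
  Ties at the threshold merge (conservative mode counting).  Cluster
  ids are ordered by (period at 0.01 h precision, then amplitude), so
  labels are deterministic under permutation of the inputs.
* **Locking.**  Ratio `p:q` = cycle-count ratio of the two readouts;
  locked iff `|p*T_A − q*T_B| < 0.01 * q*T_B` for coprime `p, q <= 4`
  *and* the peak counts over the analysis window match `p:q`.  The
  common period is `p*T_A`.
* **Onset sweeps.**  All runs share the free-running prefix
  `[0, t_c]`, which is integrated once with output exactly at every
  onset time; each run then continues with the coupling active from
  its own onset state.  This is mathematically identical to the
  stop-and-restart onset integration and dominates the cost budget:
  the standard 601-onset protocol (onsets 1000→1030 h, step 0.05 h,
  ~1000 h integrated per run) takes a few minutes on one core.
  Post-onset analysis uses the last 300 h of each run (≥ 12 cycles)
  unless configured otherwise.

## Study conditions and problem sizes

The shipped protocols use: 20 initial radii (0.1–3.9) for the
birhythmic census; 14 radii (0.1–2.7) for the trirhythmic census (the
grids avoid the unstable radii, where a trajectory started exactly on
an unstable cycle would remain there forever); the full 601-point
onset grid for the strong-coupling sweep; an 11-point onset grid for
the neutral-coupling null; an 11-step hysteresis ramp over
`mu ∈ [−1, 9]` with 480 h (20 cycles) of settling per step; a 6×4
(period × amplitude) entrainment grid with 1200 h per cell; and a 4×5
(phase × magnitude) pulse map.  Two-parameter synchronization diagrams
default to a reduced 31-point onset grid per cell, configurable, since
the full onset grid per cell is rarely informative at survey
resolution.

## What the generator does and does not emulate

The stand-ins reproduce the *dynamical structure* of the coupled
clock/cell-cycle problem — two dissimilar limit-cycle oscillators with
incommensurate free periods, switch-like induction one way and graded
repression the other, an onset time that selects initial conditions —
and the analytic normal forms provide exactly known multi-stable
attractors.  They do not reproduce the molecular detail of full
mechanistic models (dozens of species, multiple coupling arms), and
the shipped strong-coupling configuration yields mono-synchronization:
with these low-dimensional stand-ins we did not locate a parameter
region with coexisting synchronized modes, consistent with the open
question of what minimal complexity multi-synchronization requires.
Passing tests therefore demonstrate that the *census machinery*
correctly detects and separates coexisting attractors (it provably
does, on the normal forms, where trirhythmicity is exact), not that
the biological stand-ins themselves are multi-synchronizing.  Noise is
out of scope; all dynamics are deterministic.

## Known limitations

* Mode identity rests on the fingerprint distance; attractors that
  differ only in features destroyed by min–max normalisation and the
  period/amplitude summaries (e.g. identical-amplitude cycles visiting
  the same region at different speeds within one period) could be
  conflated at census resolution.
* The complex-periodic label requires the repeating pattern to fit
  within 8 cycles; longer-period bursting would be labelled aperiodic.
* Quasi-periodic and chaotic failure are distinguished only through
  the interval/height regularity heuristics, not through Lyapunov
  exponents or spectra.
* The onset-time basin sampling explores a one-dimensional curve of
  initial conditions (parametrised by the relative phase of the two
  free cycles); basins that this curve misses are invisible to the
  onset census, which is why the initial-condition census exists as a
  complementary instrument.
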