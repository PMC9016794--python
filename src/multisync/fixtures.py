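"""Deterministic test-input generator.

Produces the small synthetic signals and model configurations that the
test suite and the worked examples run on: sampled sinusoids, a
period-2 (alternating-peak) waveform, the analytic normal-form
configurations (birhythmic, trirhythmic, radial hysteresis), and the
manifests of the two calibrated biological stand-ins.  Regenerating the
bundle is byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import yaml

from ._calibration import EPS_REF, TAU_REF
from .errors import ValidationError
from .models import make_cdk_cycle, make_goodwin_clock

__all__ = ["generate_fixtures", "sinusoid_trajectory", "period2_trajectory",
           "BIRHYTHMIC_NF", "TRIRHYTHMIC_NF", "HYSTERESIS_NF",
           "STRONG_COUPLING"]

OMEGA_24 = 2.0 * math.pi / 24.0

#: Birhythmic normal form: stable cycles at radii 1 and 3 (unstable at 2),
#: no shear, so both modes share the 24 h period and differ by amplitude.
BIRHYTHMIC_NF = {"kind": "normal_form", "radii": [1.0, 2.0, 3.0],
                 "omega0": OMEGA_24, "shear": 0.0, "relax": 0.01}

#: Trirhythmic normal form: stable cycles at 0.5, 1.5, 2.5 with shear,
#: so the three modes separate in period: T = 2*pi/(omega0 + shear*rho^2).
TRIRHYTHMIC_NF = {"kind": "normal_form",
                  "radii": [0.5, 1.0, 1.5, 2.0, 2.5],
                  "omega0": OMEGA_24, "shear": 0.01, "relax": 0.01}

#: Radial hysteresis fixture: dr/dt = -k r (r^2-1)((r^2-c)^2 - mu).
HYSTERESIS_NF = {"kind": "radial_hysteresis", "c": 4.0, "mu": 1.0,
                 "relax": 0.01, "omega0": OMEGA_24}

#: Strong-coupling configuration of the calibrated stand-ins: every
#: coupling-onset time yields the same 1:1 synchronized mode.
STRONG_COUPLING = {"v_sw": 3.0, "K_ICdk1": 1.5, "h_w": 4.0, "g_r": 2.0,
                   "K_w": 0.4}


def trirhythmic_mode_periods() -> list[float]:
    """Closed-form periods of the three stable trirhythmic modes."""
    w0 = TRIRHYTHMIC_NF["omega0"]
    b = TRIRHYTHMIC_NF["shear"]
    return [2.0 * math.pi / (w0 + b * rho ** 2)
            for rho in TRIRHYTHMIC_NF["radii"][::2]]


def sinusoid_trajectory(period: float, t_end: float = 480.0,
                        dt: float = 0.05, amplitude: float = 1.0,
                        mean: float = 0.0):
    """Sampled sinusoid packaged as a two-column Trajectory."""
    from .engine import Trajectory

    t = dt * np.arange(int(round(t_end / dt)) + 1)
    x = mean + amplitude * np.sin(2.0 * math.pi * t / period)
    y = mean + amplitude * np.cos(2.0 * math.pi * t / period)
    return Trajectory(0.0, dt, np.column_stack([x, y]), ("x", "y"),
                      {"fixture": f"sinusoid_{period}h"})


def period2_trajectory(base_period: float = 10.0, t_end: float = 600.0,
                       dt: float = 0.05, high: float = 1.0, low: float = 0.6):
    """Synthetic alternating-peak waveform (period-2 pattern).

    Successive cycles alternate between peak heights ``high`` and
    ``low`` while keeping the cycle length constant, the canonical
    complex-periodic (period-doubled) signature.
    """
    from .engine import Trajectory

    t = dt * np.arange(int(round(t_end / dt)) + 1)
    phase = 2.0 * math.pi * t / base_period
    envelope = np.where((t // base_period).astype(int) % 2 == 0, high, low)
    x = envelope * 0.5 * (1.0 - np.cos(phase))
    return Trajectory(0.0, dt, np.column_stack([x, np.roll(x, 1)]), ("x", "y"),
                      {"fixture": "period2"})


def _dump(path: Path, doc: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True, default_flow_style=False)


def _write_csv(path: Path, traj) -> None:
    with open(path, "w") as fh:
        fh.write("time_h," + ",".join(traj.var_labels) + "\n")
        for t, row in zip(traj.t, traj.data):
            fh.write("%.10g,%s\n" % (t, ",".join("%.10g" % v for v in row)))


def generate_fixtures(out_dir) -> list[Path]:
    """Write the deterministic fixture bundle; returns the files written."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create fixture directory {out}: {exc}")
    written = []

    for period in (6.0, 12.0, 19.1, 24.0, 30.0):
        p = out / f"sinusoid_{str(period).replace('.', 'p')}h.csv"
        _write_csv(p, sinusoid_trajectory(period, t_end=6 * period))
        written.append(p)

    p = out / "period2_waveform.csv"
    _write_csv(p, period2_trajectory())
    written.append(p)

    configs = {
        "normal_form_birhythmic.yaml": {"model": BIRHYTHMIC_NF},
        "normal_form_trirhythmic.yaml": {
            "model": TRIRHYTHMIC_NF,
            "output": {"prefix": "trirhythmic"},
        },
        "radial_hysteresis.yaml": {
            "model": HYSTERESIS_NF,
            "sweep": {"parameter": "mu", "lo": -1.0, "hi": 9.0,
                      "n_steps": 11, "settle": 480.0},
        },
        "strong_coupling.yaml": {
            "clock": {"kind": "goodwin_clock"},
            "cycle": {"kind": "cdk_cycle"},
            "coupling": STRONG_COUPLING,
            "sweep": {"t_c_start": 1000.0, "t_c_end": 1030.0, "dt_c": 0.05,
                      "t_end": 2030.0},
        },
    }
    for name, doc in configs.items():
        p = out / name
        _dump(p, doc)
        written.append(p)

    clock = make_goodwin_clock()
    cycle = make_cdk_cycle()
    p = out / "standin_manifests.yaml"
    _dump(p, {
        "clock": clock.manifest(),
        "cycle": cycle.manifest(),
        "tuned_constants": {"tau_ref": TAU_REF, "eps_ref": EPS_REF},
        "trirhythmic_mode_periods_h": trirhythmic_mode_periods(),
    })
    written.append(p)
    return written
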