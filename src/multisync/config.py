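"""Run configuration: YAML schema, validation, and run manifests.

Configurations are nested key/value YAML documents.  Unknown keys are
rejected with an explicit listing (never silently ignored), and every
run writes a manifest that echoes the full effective configuration plus
library versions, so any output can be re-executed bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import IntegratorConfig
from .errors import ConfigError, ValidationError
from .models import (CoupledSystem, CouplingSpec, ForcingSpec,
                     OscillatorModel, make_coupled, make_forced, registry)

__all__ = ["RunConfig", "load_config", "write_manifest"]

# allowed keys per section; None marks free-form value sections
_SCHEMA: dict[str, dict | None] = {
    "model": {"kind", "params", "time_scale", "radii", "omega0", "shear",
              "relax", "c", "mu", "eps"},
    "clock": {"kind", "params", "time_scale"},
    "cycle": {"kind", "params", "eps"},
    "coupling": {"v_sw", "K_ICdk1", "h_w", "g_r", "K_w", "t_c",
                 "clock_readout", "cycle_readout"},
    "forcing": {"target", "kind", "period", "amplitude", "duty", "clip"},
    "integrator": {"rtol", "atol", "dt_out", "method", "max_step"},
    "analysis": {"discard", "analysis_window", "tol_sync", "threshold", "W"},
    "sweep": {"t_c_start", "t_c_end", "dt_c", "t_end", "t0",
              "parameter", "lo", "hi", "n_steps", "settle",
              "v_sw_grid", "K_grid", "n_onsets",
              "period_grid", "amplitude_grid", "n_phases", "target",
              "phase_grid", "magnitude_grid", "pulse_var",
              "initial_radii", "y0"},
    "simulate": {"y0", "t0", "t_end"},
    "output": {"dir", "prefix"},
    "seed": None,
}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline invocation."""

    raw: dict
    path: Path | None = None

    @property
    def seed(self) -> int | None:
        return self.raw.get("seed")

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name) or {})

    def integrator(self) -> IntegratorConfig:
        return IntegratorConfig(**self.section("integrator"))

    def build_model(self, section: str = "model") -> OscillatorModel:
        spec = self.section(section)
        if "kind" not in spec:
            raise ConfigError(f"section {section!r} needs a 'kind'")
        kind = spec.pop("kind")
        if kind not in registry:
            raise ConfigError(
                f"unknown model kind {kind!r}; registered: {sorted(registry)}")
        builder = registry[kind]
        kwargs = {}
        if kind == "normal_form":
            kwargs = {k: spec[k] for k in ("radii", "omega0", "shear", "relax")
                      if k in spec}
            if "radii" in kwargs:
                kwargs["radii"] = tuple(kwargs["radii"])
        elif kind == "radial_hysteresis":
            kwargs = {k: spec[k] for k in ("c", "mu", "relax", "omega0")
                      if k in spec}
        elif kind == "goodwin_clock":
            if "time_scale" in spec:
                kwargs["time_scale"] = spec["time_scale"]
            if spec.get("params"):
                kwargs["params"] = spec["params"]
        elif kind == "cdk_cycle":
            if "eps" in spec:
                kwargs["eps"] = spec["eps"]
            if spec.get("params"):
                kwargs["params"] = spec["params"]
        else:  # registered plugin builder: pass everything through
            kwargs = {k: v for k, v in spec.items()}
        try:
            return builder(**kwargs)
        except (TypeError, ValidationError) as exc:
            raise ConfigError(f"cannot build model {kind!r}: {exc}") from exc

    def build_coupled(self) -> CoupledSystem:
        clock = self.build_model("clock")
        cycle = self.build_model("cycle")
        coupling = CouplingSpec(**self.section("coupling"))
        return make_coupled(clock, cycle, coupling)

    def build_forced(self) -> OscillatorModel:
        model = self.build_model("model")
        forcing = ForcingSpec(**self.section("forcing"))
        return make_forced(model, forcing)


def _check_keys(raw: dict) -> None:
    unknown = []
    for key, val in raw.items():
        if key not in _SCHEMA:
            unknown.append(key)
            continue
        allowed = _SCHEMA[key]
        if allowed is not None and isinstance(val, dict):
            for sub in val:
                if sub not in allowed:
                    unknown.append(f"{key}.{sub}")
    if unknown:
        raise ConfigError("unknown configuration keys: " + ", ".join(sorted(unknown)))


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level configuration must be a mapping")
    _check_keys(raw)
    return RunConfig(raw=raw, path=path)


def _clean(obj):
    """Make a structure YAML-safe with full-precision floats."""
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_manifest(path, config: RunConfig | None = None, **records) -> None:
    """Write a structured-text manifest next to a run's outputs."""
    import numpy
    import pandas
    import scipy

    from . import __version__

    doc = {
        "multisync_version": __version__,
        "library_versions": {"numpy": numpy.__version__,
                             "scipy": scipy.__version__,
                             "pandas": pandas.__version__},
    }
    if config is not None:
        doc["config"] = _clean(config.raw)
    for key, val in records.items():
        doc[key] = _clean(val)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True, default_flow_style=False)
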