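"""Optional figure rendering for censuses and diagrams.

Matplotlib is imported lazily so headless pipelines never touch it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_onset_census", "plot_region_map", "plot_trajectory"]

_MODE_COLORS = ["tab:red", "tab:green", "tab:blue", "tab:orange", "tab:purple"]
_REGION_COLORS = {"none": "#20336b", "mono": "#9ecbe8", "bi": "#59a86b",
                  "tri": "#e8d44f", "higher": "#b4458f", "failed": "#999999"}


def plot_onset_census(census, ax=None):
    """Per-onset-time mode bars (one colored bar per run)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.2))
    df = census.assignments
    for _, row in df.iterrows():
        mode = int(row["mode"])
        color = _MODE_COLORS[mode % len(_MODE_COLORS)] if mode >= 0 else "0.8"
        ax.axvline(row["t_c"], color=color, lw=1.2)
    ax.set_xlabel("coupling onset time $t_c$ (h)")
    ax.set_yticks([])
    ax.set_title(f"{census.n_modes} mode(s): {census.classification}")
    return ax


def plot_region_map(diagram, ax=None):
    """Mono/bi/tri/no-sync region map over (v_sw, K_ICdk1)."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    if ax is None:
        _, ax = plt.subplots()
    for _, row in diagram.cells.iterrows():
        ax.scatter(row["v_sw"], row["K_ICdk1"], s=180, marker="s",
                   color=_REGION_COLORS.get(row["classification"], "k"))
    ax.set_xlabel(r"$v_{sw}$ ($\mu$M h$^{-1}$)")
    ax.set_ylabel(r"$K_{ICdk1}$ ($\mu$M)")
    seen = sorted(set(diagram.cells["classification"]))
    ax.legend(handles=[Patch(color=_REGION_COLORS.get(c, "k"), label=c)
                       for c in seen], loc="best", fontsize=8)
    return ax


def plot_trajectory(traj, variables=None, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for lab in variables or traj.var_labels:
        ax.plot(traj.t, traj[lab], label=lab, lw=0.8)
    ax.set_xlabel("time (h)")
    ax.legend(fontsize=8)
    return ax
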