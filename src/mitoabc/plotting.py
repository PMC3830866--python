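"""Coverage and trajectory figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .calibration import CoverageReport
from .model import PARAM_NAMES, Trajectory

__all__ = ["plot_coverage", "plot_trajectory"]


def plot_coverage(reports, ax=None):
    """Observed vs nominal coverage per parameter (one or more reports)."""
    if isinstance(reports, CoverageReport):
        reports = [reports]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="nominal")
    markers = ["o", "s", "^"]
    for rep in reports:
        cov = rep.coverage()
        for j, p in enumerate(PARAM_NAMES):
            label = f"set {rep.set_id} {p}" + (" (adj)" if rep.adjusted else "")
            ax.plot(rep.levels, cov[:, j], marker=markers[j % 3], ms=4, label=label)
    ax.set_xlabel("nominal coverage")
    ax.set_ylabel("observed coverage")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    return ax


def plot_trajectory(traj: Trajectory, ax=None):
    """Healthy/mutant copy counts over time, with the death day marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(traj.t, traj.y1, label="healthy (Y1)")
    ax.plot(traj.t, traj.y2, label="mutant (Y2)")
    if traj.terminated_by_death:
        ax.axvline(traj.death_time, color="r", ls=":", label="death")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("copy number")
    ax.legend()
    return ax
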