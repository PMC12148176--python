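"""Plot helpers for the reversal statistic and the group-separated curves."""

from __future__ import annotations

import numpy as np

from .group_stats import ParticipantFeatureCurve
from .kinematics import ReversalCurve
from .psychophysics import DetectionLabels


def plot_reversal_curves(curves: list[ReversalCurve], ax=None):
    """Pr_{phi,k}(tau) vs lag for several k, with the peak lag marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        ax.plot(c.tau_grid, c.pr, marker="o", label=f"k = {c.k}")
    best = max(curves, key=lambda c: np.nanmax(c.pr))
    ax.axvline(best.tau_grid[int(np.nanargmax(best.pr))], ls="--", color="grey")
    ax.set_xlabel(r"lag $\tau$ (ms)")
    ax.set_ylabel(r"$\mathrm{Pr}_{\phi,k}(\tau)$")
    ax.legend()
    return ax


def plot_group_curves(
    curves: list[ParticipantFeatureCurve],
    labels: DetectionLabels,
    threshold_freq: float,
    f_star: float | None = None,
    ax=None,
):
    """Mean cumulative feature curve per group (P> vs P<) with f* marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    membership = labels.group(threshold_freq)
    grid = curves[0].freqs
    for detected, name, color in ((True, "P$_{>f}$", "C0"), (False, "P$_{<f}$", "C3")):
        vals = [c.values for c in curves if membership[c.participant_id] == detected]
        if vals:
            ax.plot(grid, np.mean(vals, axis=0), color=color, label=name)
    if f_star is not None:
        ax.axvline(f_star, ls="--", color="grey", label=f"f* = {f_star:g} Hz")
    ax.set_xlabel("frequency f' (Hz)")
    ax.set_ylabel(curves[0].family)
    ax.legend()
    return ax
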