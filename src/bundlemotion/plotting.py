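"""Matplotlib helpers for the common diagnostic figures."""

from __future__ import annotations

import numpy as np

from .ephys import TuningCurve
from .frap import FrapFit
from .motion import Trajectory


def plot_trajectory(traj: Trajectory, ax=None, label=None, **kwargs):
    """Closed 2-D trajectory of a point over one stimulus cycle (nm)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    dc = np.append(traj.dc_nm, traj.dc_nm[0])
    dr = np.append(traj.dr_nm, traj.dr_nm[0])
    ax.plot(dc, dr, marker="o", markersize=3, label=label, **kwargs)
    ax.set_xlabel("x displacement (nm)")
    ax.set_ylabel("y displacement (nm)")
    ax.set_aspect("equal")
    return ax


def plot_tuning_curve(curve: TuningCurve, ax=None, label=None, **kwargs):
    """CM amplitude vs stimulus frequency on a log-frequency axis."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.semilogx(curve.frequencies, curve.amplitudes, marker="o",
                label=label, **kwargs)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("CM amplitude (µV)")
    return ax


def plot_frap_fit(time_s, trace, fit: FrapFit, bleach_index: int, ax=None):
    """Normalized FRAP trace with the fitted one-phase recovery overlaid."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(time_s, trace, "o", markersize=3, label="data")
    t_post = np.asarray(time_s)[bleach_index:]
    t0 = t_post[0]
    curve = fit.f_plateau - (fit.f_plateau - fit.f_post) * np.exp(
        -fit.rate * (t_post - t0))
    ax.plot(t_post, curve, "-",
            label=f"fit: $\\tau_{{1/2}}$ = {fit.tau_half:.1f} s")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized intensity")
    ax.legend()
    return ax
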