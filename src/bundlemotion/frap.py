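"""FRAP trace normalization and one-phase recovery fitting.

After a region of the stained membrane is photobleached, diffusion of
unbleached dye into the spot makes fluorescence recover toward a plateau.
The recovery is summarized by fitting a single-exponential (one-phase)
association model

    F(t) = f_plateau − (f_plateau − f_post) · exp(−k t),    k = ln 2 / τ½,

to the post-bleach samples of the baseline-normalized mean ROI intensity.
τ½, the half-time of recovery, is the reported measure of membrane lipid
mobility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import FrapTrace

__all__ = ["FrapFit", "normalize_frap", "fit_one_phase"]

_LN2 = float(np.log(2.0))


@dataclass
class FrapFit:
    """One-phase recovery parameters with fit diagnostics."""

    f_post: float
    f_plateau: float
    tau_half: float  # s
    r_squared: float
    converged: bool
    message: str = ""

    @property
    def rate(self) -> float:
        """Recovery rate k = ln2 / τ½, 1/s."""
        return _LN2 / self.tau_half


def normalize_frap(
    trace: np.ndarray | FrapTrace,
    bleach_index: Optional[int] = None,
    n_baseline: int = 10,
) -> np.ndarray:
    """Divide the whole trace by the mean of its pre-bleach baseline.

    The baseline is the ``n_baseline`` samples immediately preceding
    ``bleach_index``; after normalization their mean is exactly 1.
    """
    if isinstance(trace, FrapTrace):
        if bleach_index is None:
            bleach_index = trace.bleach_index
        values = np.asarray(trace.intensity, float)
    else:
        values = np.asarray(trace, float)
    if bleach_index is None:
        raise ValueError("bleach_index is required for a bare array trace")
    if bleach_index - n_baseline < 0 or n_baseline < 2:
        raise ValueError("need >= 2 baseline samples before the bleach")
    baseline = values[bleach_index - n_baseline:bleach_index].mean()
    if baseline <= 0:
        raise ValueError(f"baseline mean {baseline} is not positive")
    return values / baseline


def _model(t, f_post, f_plateau, k):
    return f_plateau - (f_plateau - f_post) * np.exp(-k * t)


def fit_one_phase(
    trace: np.ndarray,
    bleach_index: int,
    dt: float,
    max_iter: int = 2000,
) -> FrapFit:
    """Nonlinear least-squares fit of the one-phase recovery model.

    ``trace`` is the baseline-normalized intensity series; the fit uses the
    samples from ``bleach_index`` onward with t = 0 at the first post-bleach
    sample.  Starting values: f_post from the first post-bleach sample,
    f_plateau from the mean of the last three samples, and k from a
    log-linear regression of (f_plateau − F).  Non-convergence (including the
    degenerate flat trace, where k is unidentifiable) is reported through
    ``converged=False`` rather than an exception.
    """
    y = np.asarray(trace, float)[bleach_index:]
    if y.size < 6:
        raise ValueError("need at least 6 post-bleach samples")
    t = np.arange(y.size) * dt

    f_post0 = y[0]
    f_plateau0 = y[-3:].mean()
    span0 = f_plateau0 - f_post0
    resid = f_plateau0 + abs(span0) * 1e-3 - y
    if span0 <= 0 or np.any(resid[: y.size // 2] <= 0):
        k0 = _LN2 / (t[-1] / 4 + dt)
    else:
        half = max(y.size // 2, 3)
        slope = np.polyfit(t[:half], np.log(resid[:half]), 1)[0]
        k0 = max(-slope, 1e-6)

    try:
        popt, _ = curve_fit(
            _model, t, y, p0=[f_post0, f_plateau0, k0],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=max_iter,
        )
    except RuntimeError as exc:
        return FrapFit(f_post=f_post0, f_plateau=f_plateau0,
                       tau_half=_LN2 / k0, r_squared=np.nan,
                       converged=False, message=str(exc))

    f_post, f_plateau, k = popt
    fitted = _model(t, *popt)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    # an unidentifiable rate: flat trace (no recovery span to constrain k)
    span = f_plateau - f_post
    scale = max(abs(f_plateau), abs(f_post), 1e-12)
    if not np.isfinite(r_squared) or abs(span) < 1e-8 * scale:
        return FrapFit(f_post=float(f_post), f_plateau=float(f_plateau),
                       tau_half=float(_LN2 / k), r_squared=float(r_squared)
                       if np.isfinite(r_squared) else np.nan,
                       converged=False,
                       message="recovery span ~ 0; rate unidentifiable")
    return FrapFit(f_post=float(f_post), f_plateau=float(f_plateau),
                   tau_half=float(_LN2 / k), r_squared=r_squared,
                   converged=True)
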