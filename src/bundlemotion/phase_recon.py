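"""Stroboscopic phase reconstruction of slow-scan confocal series.

A confocal raster scan is far slower than the acoustic stimulus, so a single
frame smears many stimulus cycles across its rows.  Because every pixel's
acquisition time — and hence its stimulus phase — is known exactly, the
periodic intensity variation at each pixel can be recovered by fitting a
low-order Fourier series in stimulus phase.  Evaluating the fitted series at
equally spaced phases produces an artifact-free stroboscopic movie of one
stimulus cycle (12 phase frames by default).

For square-wave current stimuli the frames are instead split by current
polarity, yielding a positive-phase and a negative-phase mean image whose
relative shift measures electromotility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .datatypes import ScanConfig, StimulusSpec, TimedStack
from .synthgen import square_wave_sign

__all__ = [
    "TimeMap",
    "CoeffField",
    "PhaseStack",
    "PolarityPair",
    "pixel_times",
    "fit_fourier_series",
    "render_phase_stack",
    "split_by_polarity",
]


@dataclass
class TimeMap:
    """Per-pixel absolute acquisition times of a raster-scanned series.

    ``t[k, r, c] = k*frame_interval + r*line_time + c*pixel_dwell`` for a
    unidirectional forward raster.  With ``bidirectional`` set, odd rows are
    scanned right-to-left.
    """

    t: np.ndarray  # (n_frames, H, W) seconds
    scan: ScanConfig

    def phase(self, frequency: float, phase0: float = 0.0) -> np.ndarray:
        """Stimulus phase of every pixel, in [0, 2π)."""
        return np.mod(2.0 * np.pi * frequency * self.t + phase0, 2.0 * np.pi)


def pixel_times(scan: ScanConfig, bidirectional: bool = False) -> TimeMap:
    """Compute the acquisition time of every pixel in every frame."""
    k = np.arange(scan.n_frames)[:, None, None] * scan.frame_interval
    r = np.arange(scan.image_height)[None, :, None] * scan.line_time
    c = np.arange(scan.image_width)[None, None, :] * scan.pixel_dwell
    if bidirectional:
        c_rev = (scan.image_width - 1 - np.arange(scan.image_width)) * scan.pixel_dwell
        cols = np.broadcast_to(c, (1, scan.image_height, scan.image_width)).copy()
        cols[:, 1::2, :] = c_rev[None, None, :]
        c = cols
    t = k + r + c
    return TimeMap(t=t, scan=scan)


@dataclass
class CoeffField:
    """Per-pixel Fourier-series coefficients fitted against stimulus phase."""

    a0: np.ndarray  # (H, W)
    an: np.ndarray  # (n_harm, H, W), cosine coefficients
    bn: np.ndarray  # (n_harm, H, W), sine coefficients
    valid: np.ndarray  # (H, W) bool
    resid_rms: np.ndarray  # (H, W)
    n_harm: int
    stimulus: Optional[StimulusSpec] = None


@dataclass
class PhaseStack:
    """Reconstructed stroboscopic cycle: frames at equally spaced phases."""

    frames: np.ndarray  # (n_phases, H, W)
    phases: np.ndarray  # radians, 2πj/n_phases
    nm_per_pixel: float = 1.0
    valid: Optional[np.ndarray] = None  # (H, W); False where a0 was filled in
    provenance: dict = field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return self.frames.shape[0]


def fit_fourier_series(
    stack: TimedStack,
    timemap: Optional[TimeMap] = None,
    n_harm: int = 2,
    coverage_bins: int = 12,
    min_occupied_bins: int = 8,
) -> CoeffField:
    """Least-squares fit of I(φ) = a0 + Σ_n [a_n cos nφ + b_n sin nφ] per pixel.

    Each pixel contributes one intensity sample per frame, at its own known
    stimulus phase.  Pixels whose phase samples occupy fewer than
    ``min_occupied_bins`` of ``coverage_bins`` equal phase bins (or with fewer
    than 2*n_harm + 3 samples) are flagged invalid rather than fitted — a
    stimulus frequency commensurate with the scan timing concentrates samples
    in a few phase bins and leaves the design ill-conditioned.
    """
    if n_harm < 1:
        raise ValueError("n_harm must be >= 1")
    if timemap is None:
        timemap = pixel_times(stack.scan)
    phi = timemap.phase(stack.stimulus.frequency, stack.stimulus.phase0)
    n_frames, h, w = stack.frames.shape
    p = 2 * n_harm + 1

    # phase-coverage rule
    bins = np.minimum((phi / (2.0 * np.pi) * coverage_bins).astype(int),
                      coverage_bins - 1)
    occupied = np.zeros((coverage_bins, h, w), dtype=bool)
    frame_idx = bins.reshape(n_frames, -1)
    flat = occupied.reshape(coverage_bins, -1)
    np.put_along_axis(flat, frame_idx, True, axis=0)
    n_occupied = flat.sum(axis=0).reshape(h, w)
    valid = (n_occupied >= min_occupied_bins) & (n_frames >= p + 2)
    if not valid.any():
        raise ValueError(
            "no pixel satisfies the phase-coverage rule; the stimulus frequency "
            "is commensurate with the scan timing"
        )

    # design tensor (n_frames, p, H, W)
    X = np.empty((n_frames, p, h, w))
    X[:, 0] = 1.0
    for n in range(1, n_harm + 1):
        X[:, 2 * n - 1] = np.cos(n * phi)
        X[:, 2 * n] = np.sin(n * phi)

    G = np.einsum("kphw,kqhw->hwpq", X, X, optimize=True)
    b = np.einsum("kphw,khw->hwp", X, stack.frames, optimize=True)
    coef = np.full((h, w, p), np.nan)
    vi = np.where(valid)
    coef[vi] = np.linalg.solve(G[vi], b[vi][..., None])[..., 0]

    fitted = np.einsum("kphw,hwp->khw", X, np.nan_to_num(coef), optimize=True)
    resid_rms = np.sqrt(np.mean((stack.frames - fitted) ** 2, axis=0))
    resid_rms[~valid] = np.nan

    a0 = coef[..., 0]
    an = np.moveaxis(coef[..., 1::2], -1, 0)
    bn = np.moveaxis(coef[..., 2::2], -1, 0)
    return CoeffField(a0=a0, an=an, bn=bn, valid=valid, resid_rms=resid_rms,
                      n_harm=n_harm, stimulus=stack.stimulus)


def render_phase_stack(
    coeffs: CoeffField,
    n_phases: int = 12,
    nm_per_pixel: float = 1.0,
    provenance: Optional[dict] = None,
) -> PhaseStack:
    """Evaluate the fitted series at ``n_phases`` equally spaced phases.

    Invalid pixels are filled with the mean level (a0) of their nearest valid
    neighbour and remain flagged via the stack's ``valid`` mask.
    """
    if n_phases < 3:
        raise ValueError("n_phases must be >= 3")
    phases = 2.0 * np.pi * np.arange(n_phases) / n_phases
    a0 = coeffs.a0.copy()
    if not coeffs.valid.all():
        # nearest-valid-neighbour fill of the mean level
        _, (ir, ic) = ndimage.distance_transform_edt(
            ~coeffs.valid, return_indices=True
        )
        a0 = a0[ir, ic]
    an = np.nan_to_num(coeffs.an)
    bn = np.nan_to_num(coeffs.bn)
    frames = np.empty((n_phases,) + a0.shape)
    for j, phi in enumerate(phases):
        frame = a0.copy()
        acc = np.zeros_like(a0)
        for n in range(1, coeffs.n_harm + 1):
            acc += an[n - 1] * np.cos(n * phi) + bn[n - 1] * np.sin(n * phi)
        acc[~coeffs.valid] = 0.0
        frames[j] = frame + acc
    return PhaseStack(frames=frames, phases=phases, nm_per_pixel=nm_per_pixel,
                      valid=coeffs.valid.copy(), provenance=provenance or {})


@dataclass
class PolarityPair:
    """Mean images over the positive and negative half-cycles of a square wave."""

    positive: np.ndarray  # (H, W)
    negative: np.ndarray  # (H, W)
    n_positive: np.ndarray  # (H, W) sample counts
    n_negative: np.ndarray  # (H, W)
    valid: np.ndarray  # (H, W); False where either polarity has zero samples
    nm_per_pixel: float = 1.0


def split_by_polarity(
    stack: TimedStack,
    current: Optional[StimulusSpec] = None,
    timemap: Optional[TimeMap] = None,
) -> PolarityPair:
    """Average each pixel over the square-wave polarities of its sample times.

    Every pixel sample is assigned to the positive or negative half-cycle of
    the current stimulus according to its own acquisition time (half-open
    intervals: a sample at an exact transition belongs to the polarity that
    starts there).  Pixels with zero samples in one polarity are flagged.
    """
    current = current or stack.stimulus
    if current.kind != "square_current":
        raise ValueError("polarity split requires a square_current stimulus")
    if timemap is None:
        timemap = pixel_times(stack.scan)
    sgn = square_wave_sign(timemap.t, current.frequency, current.phase0)
    pos = sgn > 0
    n_pos = pos.sum(axis=0)
    n_neg = (~pos).sum(axis=0)
    with np.errstate(invalid="ignore"):
        pos_img = np.where(pos, stack.frames, 0.0).sum(axis=0) / n_pos
        neg_img = np.where(~pos, stack.frames, 0.0).sum(axis=0) / n_neg
    valid = (n_pos > 0) & (n_neg > 0)
    return PolarityPair(positive=pos_img, negative=neg_img,
                        n_positive=n_pos, n_negative=n_neg, valid=valid,
                        nm_per_pixel=stack.scan.nm_per_pixel)
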