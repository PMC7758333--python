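"""Optical-flow trajectory extraction from reconstructed phase stacks.

The reconstructed stroboscopic cycle shows the bundle at 12 equally spaced
stimulus phases.  Dense subpixel displacements of each phase frame relative
to the cycle-mean image are estimated by iterative gradient-based
(Lucas–Kanade-type) flow with a Gaussian weighting window; the cycle mean is
used as the reference frame so that errors do not accumulate around the
cycle and the mean displacement over phases is ≈ 0 by construction.

Trajectories averaged over a small kernel (3×3 or 5×5) around the bundle's
base and tip landmarks give the two measured motions; their per-phase vector
difference is the bundle deflection — the stimulus actually delivered to the
transduction channels.  Scalar amplitudes are reported as the magnitude of
the fundamental Fourier component of the trajectory projected on its
principal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .phase_recon import PhaseStack

__all__ = [
    "FlowField",
    "Trajectory",
    "smooth_stack",
    "optical_flow",
    "roi_trajectory",
    "trajectory_amplitude",
    "deflection",
    "electromotility_displacement",
]


@dataclass
class FlowField:
    """Per-phase, per-pixel displacement relative to the cycle-mean image."""

    dr: np.ndarray  # (n_phases, H, W) rows, pixels
    dc: np.ndarray  # (n_phases, H, W) cols, pixels
    valid: np.ndarray  # (H, W); False on untextured pixels
    nm_per_pixel: float = 1.0

    @property
    def n_phases(self) -> int:
        return self.dr.shape[0]


@dataclass
class Trajectory:
    """Closed per-phase 2-D displacement of an image point, in nm."""

    dr_nm: np.ndarray  # (n_phases,)
    dc_nm: np.ndarray  # (n_phases,)
    point: tuple = (0, 0)
    kernel: int = 3

    @property
    def n_phases(self) -> int:
        return self.dr_nm.size

    def __sub__(self, other: "Trajectory") -> "Trajectory":
        return deflection(self, other)


def smooth_stack(stack: PhaseStack, sigma: float) -> PhaseStack:
    """Per-frame Gaussian spatial low-pass; ``sigma=0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        frames = stack.frames.copy()
    else:
        frames = np.stack([ndimage.gaussian_filter(f, sigma) for f in stack.frames])
    return PhaseStack(frames=frames, phases=stack.phases.copy(),
                      nm_per_pixel=stack.nm_per_pixel,
                      valid=None if stack.valid is None else stack.valid.copy(),
                      provenance=dict(stack.provenance, smoothed_sigma=sigma))


def _lucas_kanade_pair(
    reference: np.ndarray,
    frame: np.ndarray,
    window_sigma: float,
    n_iter: int,
    tol: float,
    eig_ratio: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense iterative LK displacement of ``frame`` relative to ``reference``.

    Solves, at every pixel, the windowed normal equations of the brightness
    constancy constraint, then warps and re-solves until the update falls
    below ``tol`` pixels.  Returns (dr, dc, valid).
    """
    gy, gx = np.gradient(reference)

    def win(a):
        return ndimage.gaussian_filter(a, window_sigma)

    a11 = win(gy * gy)
    a12 = win(gy * gx)
    a22 = win(gx * gx)
    tr = a11 + a22
    det = a11 * a22 - a12 * a12
    # smaller eigenvalue of the structure tensor; texture criterion
    lam_min = 0.5 * (tr - np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0)))
    valid = lam_min > eig_ratio * lam_min.max()
    if not valid.any():
        raise ValueError("degenerate structure tensor everywhere: no texture")

    h, w = reference.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    dr = np.zeros_like(reference)
    dc = np.zeros_like(reference)
    det_safe = np.where(valid, det, 1.0)
    for _ in range(n_iter):
        warped = ndimage.map_coordinates(frame, [rows + dr, cols + dc],
                                         order=3, mode="nearest")
        e = warped - reference
        b1 = win(gy * e)
        b2 = win(gx * e)
        # frame(x) = ref(x - d)  =>  residual gradient step is -A^{-1} b
        ur = -(a22 * b1 - a12 * b2) / det_safe
        uc = -(a11 * b2 - a12 * b1) / det_safe
        ur = np.where(valid, ur, 0.0)
        uc = np.where(valid, uc, 0.0)
        dr += ur
        dc += uc
        if max(np.abs(ur).max(), np.abs(uc).max()) < tol:
            break
    return dr, dc, valid


def optical_flow(
    stack: PhaseStack,
    window_sigma: float = 2.0,
    n_iter: int = 20,
    tol: float = 1.0e-3,
    eig_ratio: float = 1.0e-3,
) -> FlowField:
    """Subpixel displacement of every pixel in every phase frame.

    Displacements are measured relative to the cycle-mean image with an
    iterative Lucas–Kanade scheme (Gaussian window of sd ``window_sigma`` px,
    at most ``n_iter`` warp iterations, convergence at ``tol`` px).  Pixels
    whose windowed structure tensor is near-singular (untextured) are flagged
    invalid and carry zero flow.
    """
    if stack.n_phases < 3:
        raise ValueError("optical flow needs at least 3 phase frames")
    reference = stack.frames.mean(axis=0)
    dr = np.empty_like(stack.frames)
    dc = np.empty_like(stack.frames)
    valid = None
    for j in range(stack.n_phases):
        r, c, v = _lucas_kanade_pair(reference, stack.frames[j], window_sigma,
                                     n_iter, tol, eig_ratio)
        dr[j], dc[j] = r, c
        valid = v if valid is None else (valid & v)
    if stack.valid is not None:
        valid = valid & stack.valid
    return FlowField(dr=dr, dc=dc, valid=valid, nm_per_pixel=stack.nm_per_pixel)


def roi_trajectory(
    flow: FlowField,
    point: tuple,
    kernel: int = 3,
    nm_per_pixel: float | None = None,
) -> Trajectory:
    """Average the per-pixel trajectories over a kernel around ``point``.

    ``kernel`` is 3 or 5 (a 3×3 or 5×5 region).  At least half of the
    kernel's pixels must be valid; the mean is taken over the valid ones.
    """
    if kernel not in (3, 5):
        raise ValueError("kernel must be 3 or 5")
    nm = flow.nm_per_pixel if nm_per_pixel is None else nm_per_pixel
    r0, c0 = int(round(point[0])), int(round(point[1]))
    half = kernel // 2
    h, w = flow.dr.shape[1:]
    if not (half <= r0 < h - half and half <= c0 < w - half):
        raise ValueError(f"kernel {kernel}x{kernel} around {point} does not fit "
                         f"inside a {h}x{w} image")
    sl = np.s_[r0 - half:r0 + half + 1, c0 - half:c0 + half + 1]
    mask = flow.valid[sl]
    n_valid = int(mask.sum())
    if n_valid < (kernel * kernel + 1) // 2:
        raise ValueError(
            f"only {n_valid} of {kernel * kernel} kernel pixels are valid at {point}"
        )
    dr = flow.dr[(np.s_[:],) + sl][:, mask].mean(axis=1)
    dc = flow.dc[(np.s_[:],) + sl][:, mask].mean(axis=1)
    return Trajectory(dr_nm=dr * nm, dc_nm=dc * nm, point=(r0, c0), kernel=kernel)


def trajectory_amplitude(traj: Trajectory) -> float:
    """Scalar motion amplitude of a cyclic trajectory, in nm.

    The trajectory is projected on its principal axis (the direction of
    largest variance) and the magnitude of the fundamental Fourier component
    of the projected signal is returned.  For x(φ) = A sin φ this equals A;
    for a circular trajectory of radius A it also equals A.  This definition
    is robust to per-phase noise; it is not half the peak-to-peak excursion.
    """
    n = traj.n_phases
    if n < 3:
        raise ValueError("trajectory must have at least 3 phases")
    pts = np.stack([traj.dr_nm, traj.dc_nm], axis=1)
    pts = pts - pts.mean(axis=0)
    # principal axis via SVD
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    x = pts @ vt[0]
    spec = np.fft.rfft(x)
    return float(2.0 * np.abs(spec[1]) / n)


def deflection(tip: Trajectory, base: Trajectory) -> Trajectory:
    """Per-phase vector difference tip − base (the bundle deflection)."""
    if tip.n_phases != base.n_phases:
        raise ValueError(
            f"phase mismatch: tip has {tip.n_phases} phases, base {base.n_phases}"
        )
    return Trajectory(dr_nm=tip.dr_nm - base.dr_nm,
                      dc_nm=tip.dc_nm - base.dc_nm,
                      point=tip.point, kernel=tip.kernel)


def electromotility_displacement(
    pos_image: np.ndarray,
    neg_image: np.ndarray,
    roi: tuple | None = None,
    nm_per_pixel: float = 1.0,
    upsample_factor: int = 200,
) -> float:
    """Rigid subpixel shift between polarity-mean images, in nm.

    The positive- and negative-current mean images differ by a rigid
    translation equal to the electromotility step; it is estimated by
    upsampled phase cross-correlation within the ROI (``roi`` is a
    (row_slice, col_slice) pair; whole image if omitted).
    """
    if roi is not None:
        pos_image = pos_image[roi]
        neg_image = neg_image[roi]
    if pos_image.std() == 0 or neg_image.std() == 0:
        raise ValueError("untextured ROI: no structure to register")
    # plain cross-correlation: spectral whitening amplifies noise on these
    # smooth, low-texture images and is disabled
    shift, _, _ = phase_cross_correlation(pos_image, neg_image,
                                          upsample_factor=upsample_factor,
                                          normalization=None)
    return float(np.hypot(*shift) * nm_per_pixel)
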