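"""Shared data containers for the hair-bundle measurement pipeline.

These are plain dataclasses with validation in ``__post_init__``.  They carry
the acquisition geometry and stimulus bookkeeping that every downstream stage
relies on: in a phase-stamped confocal acquisition the scanner raster is slow
compared with the acoustic stimulus, so the exact acquisition time of every
pixel — frame start + row * line time + column * pixel dwell — is what allows
each pixel to be assigned a stimulus phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ScanConfig",
    "StimulusSpec",
    "MotionTruth",
    "TimedStack",
    "FrapTruth",
    "FrapTrace",
    "Recording",
    "BundleScene",
]


@dataclass(frozen=True)
class ScanConfig:
    """Raster-scan timing and calibration of a confocal acquisition.

    Defaults emulate a 37-frame series taking roughly 40 s in total, the
    operating point of slow-scan stroboscopic imaging of hair bundles.  The
    per-pixel dwell and line times are plausible confocal values chosen so the
    timing invariants hold; the acquisition hardware's true internals are not
    modelled.
    """

    image_height: int = 64
    image_width: int = 64
    pixel_dwell: float = 1.0e-5  # s
    line_time: float = 1.0e-3  # s
    frame_interval: float = 40.0 / 37.0  # s
    n_frames: int = 37
    nm_per_pixel: float = 100.0

    def __post_init__(self) -> None:
        if self.line_time < self.image_width * self.pixel_dwell:
            raise ValueError(
                "line_time must be >= image_width * pixel_dwell "
                f"({self.line_time} < {self.image_width * self.pixel_dwell})"
            )
        if self.frame_interval < self.image_height * self.line_time:
            raise ValueError(
                "frame_interval must be >= image_height * line_time "
                f"({self.frame_interval} < {self.image_height * self.line_time})"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.nm_per_pixel <= 0:
            raise ValueError("nm_per_pixel must be positive")


@dataclass(frozen=True)
class StimulusSpec:
    """Periodic stimulus: an acoustic tone or a square-wave current.

    ``level`` is dB SPL for tones and µA for currents; it is metadata carried
    along for bookkeeping and never enters the phase computation.
    """

    kind: str = "tone"  # "tone" | "square_current"
    frequency: float = 220.0  # Hz
    level: float = 80.0  # dB SPL (tone) or µA (square_current)
    phase0: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.kind not in ("tone", "square_current"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("direction vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class MotionTruth:
    """Planted ground-truth motion of a vibrating hair bundle.

    Base and tip each follow their own sinusoidal law; the implied bundle
    deflection is the per-phase vector difference tip − base.  ``em_step`` is
    the peak-to-peak displacement of the square-wave (electromotility) motion,
    applied as a rigid translation along ``em_direction``.

    Directions are (row, col) unit vectors in image coordinates.
    """

    base_amplitude: float = 98.0  # nm
    tip_amplitude: float = 90.0  # nm
    base_phase: float = 0.0  # rad
    tip_phase: float = 0.0  # rad
    base_direction: tuple = (1.0, 0.0)
    tip_direction: tuple = (1.0, 0.0)
    em_step: float = 0.0  # nm, square-wave displacement (peak-to-peak)
    em_direction: Optional[tuple] = None  # defaults to base_direction

    def __post_init__(self) -> None:
        if self.base_amplitude < 0 or self.tip_amplitude < 0 or self.em_step < 0:
            raise ValueError("amplitudes must be >= 0")
        object.__setattr__(self, "base_direction", tuple(_unit(self.base_direction)))
        object.__setattr__(self, "tip_direction", tuple(_unit(self.tip_direction)))
        if self.em_direction is not None:
            object.__setattr__(self, "em_direction", tuple(_unit(self.em_direction)))

    @property
    def em_dir(self) -> np.ndarray:
        d = self.em_direction if self.em_direction is not None else self.base_direction
        return np.asarray(d, dtype=float)


@dataclass
class BundleScene:
    """Static band-limited template image with base/tip landmarks (row, col)."""

    image: np.ndarray
    base: tuple
    tip: tuple

    @property
    def axis(self) -> np.ndarray:
        """Unit vector pointing from base to tip, (row, col)."""
        d = np.asarray(self.tip, float) - np.asarray(self.base, float)
        return d / np.linalg.norm(d)


@dataclass
class TimedStack:
    """A raster-scanned frame series with known per-pixel acquisition times."""

    frames: np.ndarray  # (n_frames, H, W), intensities >= 0
    scan: ScanConfig
    stimulus: StimulusSpec
    truth: Optional[MotionTruth] = None
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        k, h, w = self.frames.shape
        if (k, h, w) != (self.scan.n_frames, self.scan.image_height, self.scan.image_width):
            raise ValueError(
                f"frames shape {self.frames.shape} does not match scan config "
                f"({self.scan.n_frames}, {self.scan.image_height}, {self.scan.image_width})"
            )
        if np.any(self.frames < 0):
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class FrapTruth:
    """Ground truth for a one-phase fluorescence-recovery trace.

    ``tau_half`` is the half-time of recovery: at t = tau_half after the
    bleach, fluorescence has recovered half of the (f_plateau − f_post) span.
    """

    f_pre: float = 1.0
    f_post: float = 0.35
    f_plateau: float = 0.85
    tau_half: float = 22.0  # s
    n_baseline: int = 10
    n_recovery: int = 30
    dt: float = 1.0  # s, 1 or 3 in generated fixtures

    def __post_init__(self) -> None:
        if not (self.f_post <= self.f_plateau <= self.f_pre):
            raise ValueError("require f_post <= f_plateau <= f_pre")
        if self.tau_half <= 0:
            raise ValueError("tau_half must be positive")
        if self.n_baseline < 1 or self.n_recovery < 1:
            raise ValueError("sample counts must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class FrapTrace:
    """Sampled FRAP intensity trace with the bleach event marked."""

    time_s: np.ndarray
    intensity: np.ndarray
    bleach_index: int
    truth: Optional[FrapTruth] = None


@dataclass
class Recording:
    """A sampled voltage trace (CM or CAP) with stimulus metadata."""

    samples: np.ndarray  # µV
    sample_rate: float  # Hz
    stimulus: StimulusSpec
    epoch_markers: Optional[np.ndarray] = None  # sample indices, strictly increasing
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.epoch_markers is not None:
            self.epoch_markers = np.asarray(self.epoch_markers, dtype=int)
            if np.any(np.diff(self.epoch_markers) <= 0):
                raise ValueError("epoch_markers must be strictly increasing")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate
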