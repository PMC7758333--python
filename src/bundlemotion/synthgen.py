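"""Synthetic acquisition generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here: raster
scans of a vibrating hair bundle (tone or square-wave current stimulation),
FRAP traces, cochlear-microphonic tone-burst recordings, and compound action
potential epochs.  The planted parameters travel with the output so that
downstream recovery can be tested without any external data.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import (
    BundleScene,
    FrapTrace,
    FrapTruth,
    MotionTruth,
    Recording,
    ScanConfig,
    StimulusSpec,
    TimedStack,
)

__all__ = [
    "BundleGeometry",
    "make_bundle_scene",
    "simulate_scan",
    "simulate_frap_trace",
    "simulate_cm_recording",
    "simulate_cap_recording",
    "square_wave_sign",
    "CM_FREQUENCIES",
]

#: Default CM tuning-curve frequency grid (Hz), spanning the 60–820 Hz tone
#: burst series used for low-frequency microphonic tuning curves.
CM_FREQUENCIES = (60.0, 100.0, 140.0, 180.0, 220.0, 300.0, 420.0, 580.0, 820.0)


@dataclass(frozen=True)
class BundleGeometry:
    """Placement of the synthetic bundle in the image, (row, col) pixels."""

    base: tuple = (44.0, 22.0)
    tip: tuple = (20.0, 42.0)
    ridge_sigma: float = 3.0  # px, transverse width of the bundle ridge
    texture_sigma: float = 1.5  # px, band-limit of the speckle texture
    texture_strength: float = 0.35  # relative to ridge contrast


def make_bundle_scene(
    height: int = 64,
    width: int = 64,
    geometry: BundleGeometry | None = None,
    seed: int = 0,
) -> BundleScene:
    """Build a smooth, band-limited template of a stained hair bundle.

    The template is a bright ridge running from the base landmark to the tip
    landmark, overlaid with low-pass-filtered speckle so that optical flow has
    texture to lock onto.  Deterministic given ``seed``.

    Raises ``ValueError`` if either landmark comes within 5 px of the image
    border (displaced sampling would leave interpolation support).
    """
    geometry = geometry or BundleGeometry()
    margin = 5.0
    for name, (r, c) in (("base", geometry.base), ("tip", geometry.tip)):
        if not (margin <= r <= height - 1 - margin and margin <= c <= width - 1 - margin):
            raise ValueError(
                f"{name} landmark {(r, c)} violates the {margin:.0f}-pixel margin "
                f"inside a {height}x{width} image"
            )

    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:height, 0:width].astype(float)
    p0 = np.asarray(geometry.base, float)
    p1 = np.asarray(geometry.tip, float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    axis = axis / length

    # distance from each pixel to the base->tip segment
    rel = np.stack([rows - p0[0], cols - p0[1]], axis=-1)
    s = np.clip(rel @ axis, 0.0, length)
    foot = p0 + s[..., None] * axis
    dist = np.hypot(rows - foot[..., 0], cols - foot[..., 1])
    ridge = np.exp(-0.5 * (dist / geometry.ridge_sigma) ** 2)

    texture = ndimage.gaussian_filter(rng.standard_normal((height, width)),
                                      geometry.texture_sigma)
    texture = texture / (texture.std() + 1e-12)

    image = 100.0 + 120.0 * ridge * (1.0 + geometry.texture_strength * texture)
    # final band-limiting pass keeps the template smooth at the pixel scale
    image = ndimage.gaussian_filter(image, 1.0)
    image = np.clip(image, 0.0, None)
    return BundleScene(image=image, base=tuple(geometry.base), tip=tuple(geometry.tip))


def square_wave_sign(t: np.ndarray, frequency: float, phase0: float = 0.0) -> np.ndarray:
    """Polarity (+1/−1) of a square wave at times ``t``.

    The positive half-cycle occupies the half-open interval [0, T/2) of each
    period (phase0 shifts the origin), so a sample landing exactly on a
    transition belongs to the polarity that begins at that instant.
    """
    frac = np.mod(np.asarray(t, float) * frequency + phase0 / (2.0 * np.pi), 1.0)
    return np.where(frac < 0.5, 1.0, -1.0)


def _displacement_field(
    scene: BundleScene,
    truth: MotionTruth,
    stimulus: StimulusSpec,
    t: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    nm_per_pixel: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel displacement (dr, dc) in pixels at per-pixel times ``t``.

    Base and tip move by their own laws; interior pixels are displaced by
    linear interpolation along the bundle axis (the base and tip trajectories
    are the two constrained quantities; the interior is unconstrained and a
    linear blend is the simplest consistent choice).  Pixels beyond the
    landmarks are clamped to the nearest landmark's law.
    """
    p0 = np.asarray(scene.base, float)
    p1 = np.asarray(scene.tip, float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    axis = axis / length
    w = np.clip(((rows - p0[0]) * axis[0] + (cols - p0[1]) * axis[1]) / length, 0.0, 1.0)

    if stimulus.kind == "tone":
        arg = 2.0 * np.pi * stimulus.frequency * t + stimulus.phase0
        a_b = truth.base_amplitude / nm_per_pixel
        a_t = truth.tip_amplitude / nm_per_pixel
        d_base = a_b * np.sin(arg + truth.base_phase)
        d_tip = a_t * np.sin(arg + truth.tip_phase)
        bd = np.asarray(truth.base_direction)
        td = np.asarray(truth.tip_direction)
        dr = (1.0 - w) * d_base * bd[0] + w * d_tip * td[0]
        dc = (1.0 - w) * d_base * bd[1] + w * d_tip * td[1]
    elif stimulus.kind == "square_current":
        step = 0.5 * truth.em_step / nm_per_pixel
        sgn = square_wave_sign(t, stimulus.frequency, stimulus.phase0)
        ed = truth.em_dir
        dr = step * sgn * ed[0]
        dc = step * sgn * ed[1]
    else:  # pragma: no cover - guarded by StimulusSpec
        raise ValueError(f"unknown stimulus kind {stimulus.kind!r}")
    return dr, dc


def simulate_scan(
    scene: BundleScene,
    truth: MotionTruth,
    scan: ScanConfig,
    stimulus: StimulusSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    poisson: bool = False,
) -> TimedStack:
    """Raster-scan the moving scene into a TimedStack.

    Each pixel is acquired at its own instant t(k, r, c); its intensity is
    the static template resampled (cubic interpolation) at the position
    displaced by the planted motion law at that instant, plus additive
    Gaussian noise of sd ``noise_sd`` (truncated at zero).  With ``poisson``
    set, Poisson photon noise is applied before the Gaussian read noise.
    """
    from .phase_recon import pixel_times  # local import avoids a cycle

    if stimulus.kind == "tone" and not (60.0 <= stimulus.frequency <= 1000.0):
        raise ValueError("imaging fixtures use tone frequencies in [60, 1000] Hz")
    max_amp_nm = max(truth.base_amplitude, truth.tip_amplitude, truth.em_step)
    limit_nm = 0.25 * scan.image_width * scan.nm_per_pixel
    if max_amp_nm > limit_nm:
        raise ValueError(
            f"planted amplitude {max_amp_nm:.0f} nm exceeds 25% of image width "
            f"({limit_nm:.0f} nm); the template would leave interpolation support"
        )

    tm = pixel_times(scan)
    rng = np.random.default_rng(seed)
    h, wdt = scan.image_height, scan.image_width
    rows, cols = np.mgrid[0:h, 0:wdt].astype(float)

    frames = np.empty((scan.n_frames, h, wdt), dtype=float)
    for k in range(scan.n_frames):
        dr, dc = _displacement_field(scene, truth, stimulus, tm.t[k], rows, cols,
                                     scan.nm_per_pixel)
        # pull-back warp: the scene moved by +d, so sample it at x - d
        frames[k] = ndimage.map_coordinates(
            scene.image, [rows - dr, cols - dc], order=3, mode="reflect"
        )
    if poisson:
        frames = rng.poisson(np.clip(frames, 0.0, None)).astype(float)
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, None)
    return TimedStack(frames=frames, scan=scan, stimulus=stimulus, truth=truth,
                      noise_sd=noise_sd, seed=seed)


def simulate_frap_trace(truth: FrapTruth, noise_sd: float = 0.0, seed: int = 0) -> FrapTrace:
    """Generate a FRAP intensity trace from one-phase recovery ground truth.

    The trace holds ``n_baseline`` pre-bleach samples at ``f_pre`` followed by
    ``n_recovery`` samples of F(t) = f_plateau − (f_plateau − f_post)·2^(−t/τ½)
    with t = 0 at the first post-bleach sample, step ``dt``.
    """
    rng = np.random.default_rng(seed)
    t_base = (np.arange(truth.n_baseline) - truth.n_baseline) * truth.dt
    t_rec = np.arange(truth.n_recovery) * truth.dt
    f_base = np.full(truth.n_baseline, truth.f_pre)
    span = truth.f_plateau - truth.f_post
    f_rec = truth.f_plateau - span * np.power(2.0, -t_rec / truth.tau_half)
    time = np.concatenate([t_base, t_rec])
    intensity = np.concatenate([f_base, f_rec])
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.size)
    return FrapTrace(time_s=time, intensity=intensity,
                     bleach_index=truth.n_baseline, truth=truth)


def _hanning_gated_burst(
    frequency: float,
    amplitude: float,
    sample_rate: float,
    ramp_s: float,
    n_cycles: int,
    phase0: float = 0.0,
) -> np.ndarray:
    """Tone burst: sinusoid with raised-cosine (Hanning) rise/fall gates."""
    steady_s = n_cycles / frequency
    n_ramp = int(round(ramp_s * sample_rate))
    n_steady = int(round(steady_s * sample_rate))
    n_total = n_steady + 2 * n_ramp
    t = np.arange(n_total) / sample_rate
    sig = amplitude * np.sin(2.0 * np.pi * frequency * t + phase0)
    env = np.ones(n_total)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return sig * env


def simulate_cm_recording(
    tuning_truth: dict,
    level: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_rate: float = 10_000.0,
    ramp_s: float = 1.0e-3,
    min_cycles: int = 40,
) -> list[Recording]:
    """Simulate CM tone-burst recordings across a tuning-curve frequency grid.

    ``tuning_truth`` maps stimulus frequency (Hz) to the planted steady-state
    CM amplitude (µV).  Each recording is a Hanning-gated sinusoid at 10 kHz
    whose steady-state portion contains an integer number of cycles, plus
    independent Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    recordings = []
    for f in sorted(tuning_truth):
        if f >= sample_rate / 4.0:
            raise ValueError(
                f"stimulus frequency {f} Hz exceeds the Nyquist/2 margin "
                f"({sample_rate / 4.0:.0f} Hz at {sample_rate:.0f} Hz sampling)"
            )
        amp = float(tuning_truth[f])
        n_cycles = max(min_cycles, int(np.ceil(0.2 * f)))
        sig = _hanning_gated_burst(f, amp, sample_rate, ramp_s, n_cycles)
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, size=sig.size)
        stim = StimulusSpec(kind="tone", frequency=float(f), level=level)
        recordings.append(Recording(samples=sig, sample_rate=sample_rate,
                                    stimulus=stim,
                                    meta={"ramp_s": ramp_s, "n_cycles": n_cycles,
                                          "planted_amplitude_uV": amp}))
    return recordings


def cap_template(
    n1_latency_ms: float,
    n1_amp: float,
    n2_latency_ms: float,
    n2_amp: float,
    sample_rate: float = 100_000.0,
    epoch_ms: float = 10.0,
    trough_width_ms: float = 0.3,
) -> np.ndarray:
    """Noise-free single-epoch CAP waveform: two Gaussian negative troughs."""
    t_ms = np.arange(int(round(epoch_ms * sample_rate / 1000.0))) / sample_rate * 1000.0
    w = trough_width_ms
    wave = -n1_amp * np.exp(-0.5 * ((t_ms - n1_latency_ms) / w) ** 2)
    wave -= n2_amp * np.exp(-0.5 * ((t_ms - n2_latency_ms) / w) ** 2)
    return wave


def simulate_cap_recording(
    n1_latency_ms: float = 1.5,
    n1_amp: float = 30.0,
    n2_latency_ms: float = 2.5,
    n2_amp: float = 15.0,
    n_reps: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_rate: float = 100_000.0,
    epoch_ms: float = 10.0,
    trough_width_ms: float = 0.3,
) -> Recording:
    """Simulate a CAP recording of ``n_reps`` identical epochs plus noise.

    Each epoch is a fixed biphasic waveform with Gaussian-shaped negative
    troughs (N1 and N2) at the stated latencies and magnitudes; independent
    Gaussian noise is drawn per repetition.  Epoch markers index the start of
    each repetition for downstream triggered averaging.
    """
    if not (0 < n1_latency_ms < n2_latency_ms):
        raise ValueError("require 0 < n1_latency < n2_latency")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if (n2_latency_ms - n1_latency_ms) < 2.0 * trough_width_ms:
        raise ValueError(
            f"troughs {n1_latency_ms} and {n2_latency_ms} ms are closer than "
            f"2x their width ({trough_width_ms} ms); unresolvable"
        )
    rng = np.random.default_rng(seed)
    epoch = cap_template(n1_latency_ms, n1_amp, n2_latency_ms, n2_amp,
                         sample_rate, epoch_ms, trough_width_ms)
    n = epoch.size
    samples = np.tile(epoch, n_reps)
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=samples.size)
    markers = np.arange(n_reps) * n
    stim = StimulusSpec(kind="tone", frequency=8000.0, level=60.0)
    return Recording(samples=samples, sample_rate=sample_rate, stimulus=stim,
                     epoch_markers=markers,
                     meta={"n1_latency_ms": n1_latency_ms, "n1_amp": n1_amp,
                           "n2_latency_ms": n2_latency_ms, "n2_amp": n2_amp,
                           "epoch_ms": epoch_ms,
                           "trough_width_ms": trough_width_ms})
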