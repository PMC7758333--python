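"""Cochlear microphonic and compound action potential analysis.

CM: tone-burst recordings are Fourier-transformed over an integer-cycle
steady-state window and the amplitude at the stimulus frequency is tracked
across the 60–820 Hz series, giving a tuning curve whose maximum defines the
best frequency.

CAP: epoch-triggered averaging over stimulus repetitions after zero-phase
band-pass filtering, then extraction of the first (N1) and second (N2)
negative troughs — their latencies and baseline-to-trough magnitudes are the
standard features of auditory-nerve sensitivity.

Drug time courses are normalized to the pre-injection mean, with the
injection at time zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .datatypes import Recording

__all__ = [
    "TuningCurve",
    "CapFeatures",
    "TimeCourse",
    "spectral_amplitude",
    "build_tuning_curve",
    "normalize_time_course",
    "cap_preprocess",
    "cap_features",
    "cap_io_function",
]


@dataclass
class TuningCurve:
    """CM amplitude versus stimulus frequency."""

    frequencies: np.ndarray  # Hz, sorted ascending
    amplitudes: np.ndarray  # µV

    @property
    def peak_amplitude(self) -> float:
        return float(np.max(self.amplitudes))

    @property
    def best_frequency(self) -> float:
        # ties resolve to the lowest frequency (first argmax on sorted grid)
        return float(self.frequencies[int(np.argmax(self.amplitudes))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_hz": self.frequencies, "amp_uV": self.amplitudes})


@dataclass
class CapFeatures:
    """N1/N2 trough latencies (ms) and baseline-to-trough magnitudes (µV)."""

    n1_latency_ms: float
    n1_amplitude: float
    n2_latency_ms: float
    n2_amplitude: float

    def __post_init__(self) -> None:
        if not (0 < self.n1_latency_ms < self.n2_latency_ms):
            raise ValueError("require 0 < n1_latency < n2_latency")


@dataclass
class TimeCourse:
    """Series normalized to its pre-injection mean; injection at t = 0 min."""

    times: np.ndarray  # minutes
    values: np.ndarray  # dimensionless


def _steady_window(rec: Recording, f0: float, ramp_s: float) -> np.ndarray:
    """Central integer-cycle span of the burst, excluding the gating ramps."""
    fs = rec.sample_rate
    n_ramp = int(round(ramp_s * fs))
    core = rec.samples[n_ramp: rec.samples.size - n_ramp]
    n_cycles = int(np.floor(core.size * f0 / fs))
    if n_cycles < 1:
        raise ValueError("analysis window shorter than one stimulus cycle")
    n_window = int(round(n_cycles * fs / f0))
    start = (core.size - n_window) // 2
    return core[start:start + n_window]


def spectral_amplitude(rec: Recording, f0: float, ramp_s: float = 1.0e-3) -> float:
    """Single-sided DFT amplitude at the bin nearest ``f0``, in µV.

    The analysis window is the central span of the burst containing an
    integer number of cycles of ``f0`` and excluding the 1 ms gating ramps,
    so a pure sinusoid of amplitude A returns A with no leakage correction.
    """
    if f0 >= rec.sample_rate / 2.0:
        raise ValueError(f"{f0} Hz is above Nyquist ({rec.sample_rate / 2:.0f} Hz)")
    win = _steady_window(rec, f0, ramp_s)
    spec = np.fft.rfft(win)
    freqs = np.fft.rfftfreq(win.size, 1.0 / rec.sample_rate)
    k = int(np.argmin(np.abs(freqs - f0)))
    at_nyquist = win.size % 2 == 0 and k == win.size // 2
    scale = 1.0 if (k == 0 or at_nyquist) else 2.0
    return float(scale * np.abs(spec[k]) / win.size)


def build_tuning_curve(recordings: list[Recording], ramp_s: float = 1.0e-3) -> TuningCurve:
    """CM amplitude per stimulus frequency across a sorted recording series."""
    freqs = np.array([r.stimulus.frequency for r in recordings], dtype=float)
    if freqs.size == 0:
        raise ValueError("no recordings")
    if np.unique(freqs).size != freqs.size:
        raise ValueError("duplicate stimulus frequencies in the series")
    order = np.argsort(freqs)
    amps = np.array([spectral_amplitude(recordings[i], freqs[i], ramp_s)
                     for i in order])
    return TuningCurve(frequencies=freqs[order], amplitudes=amps)


def normalize_time_course(times, values, injection_time: float = 0.0) -> TimeCourse:
    """Normalize a drug time course to the pre-injection mean.

    Times are shifted so the injection is at 0; values are divided by the
    mean of all pre-injection (t < 0 after shifting) values.
    """
    times = np.asarray(times, float) - injection_time
    values = np.asarray(values, float)
    pre = values[times < 0]
    if pre.size < 2:
        raise ValueError("need at least 2 pre-injection values")
    m = pre.mean()
    if m <= 0:
        raise ValueError(f"pre-injection mean {m} is not positive")
    return TimeCourse(times=times, values=values / m)


def cap_preprocess(
    rec: Recording,
    band: tuple = (3.0, 3000.0),
    n_reps: int | None = None,
) -> np.ndarray:
    """Epoch-triggered average followed by zero-phase band-pass filtering.

    The first ``n_reps`` epochs (all, if omitted) are averaged on the
    recorded epoch markers, then a 4th-order Butterworth band-pass (defaults
    3 Hz–3 kHz) is applied forward-backward to the averaged waveform.
    Averaging and linear filtering commute for stationary epochs, and
    filtering the short average avoids smearing the slow high-pass edge
    transient of the long raw trace across epochs.  The recording amplifier
    gain is metadata and never applied to the samples.
    """
    if rec.epoch_markers is None or rec.epoch_markers.size == 0:
        raise ValueError("recording carries no epoch markers")
    lo, hi = band
    nyq = rec.sample_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} must lie within (0, {nyq:.0f}) Hz")

    markers = rec.epoch_markers
    n_avail = markers.size
    n_reps = n_avail if n_reps is None else n_reps
    if n_avail < n_reps:
        raise ValueError(f"only {n_avail} epochs available, {n_reps} requested")
    epoch_len = int(np.min(np.diff(markers))) if markers.size > 1 \
        else rec.samples.size - markers[0]
    epochs = np.stack([rec.samples[m:m + epoch_len] for m in markers[:n_reps]])
    avg = epochs.mean(axis=0)

    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.sample_rate,
                        output="sos")
    return signal.sosfiltfilt(sos, avg)


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabolic interpolation around sample ``i``; (offset, value)."""
    if i == 0 or i == y.size - 1:
        return 0.0, float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return 0.0, float(b)
    off = 0.5 * (a - c) / denom
    val = b - 0.25 * (a - c) * off
    return float(off), float(val)


def cap_features(
    waveform: np.ndarray,
    sample_rate: float,
    search_window: tuple = (0.5, 4.0),
    baseline_window: tuple | None = None,
) -> CapFeatures:
    """Extract N1 and N2 from an averaged CAP waveform.

    N1 is the first local minimum inside ``search_window`` (ms); N2 the next
    local minimum after it.  Amplitudes are |baseline − trough| with the
    baseline taken as the mean of the pre-window (default: everything before
    the search window).  Trough latencies are refined to subsample precision
    by 3-point parabolic interpolation.
    """
    waveform = np.asarray(waveform, float)
    t_ms = np.arange(waveform.size) / sample_rate * 1000.0
    lo, hi = search_window
    if baseline_window is None:
        base_mask = t_ms < lo
    else:
        base_mask = (t_ms >= baseline_window[0]) & (t_ms < baseline_window[1])
    baseline = float(waveform[base_mask].mean()) if base_mask.any() else 0.0

    in_win = np.where((t_ms >= lo) & (t_ms <= hi))[0]
    if in_win.size < 3:
        raise ValueError(f"search window {search_window} ms holds too few samples")
    seg = waveform[in_win]
    minima = np.where((seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:]))[0] + 1
    # require a real trough, below baseline
    minima = minima[seg[minima] < baseline]
    if minima.size < 1:
        raise ValueError(
            f"no qualifying trough in window {search_window} ms below baseline "
            f"{baseline:.3g} µV"
        )

    def refine(local_idx: int) -> tuple[float, float]:
        i = in_win[local_idx]
        off, val = _parabolic_refine(waveform, i)
        return (i + off) / sample_rate * 1000.0, abs(baseline - val)

    n1_lat, n1_amp = refine(int(minima[0]))
    later = minima[minima > minima[0] + 1]
    if later.size < 1:
        raise ValueError(
            f"no second trough (N2) after N1 in window {search_window} ms"
        )
    n2_lat, n2_amp = refine(int(later[0]))
    return CapFeatures(n1_latency_ms=n1_lat, n1_amplitude=n1_amp,
                       n2_latency_ms=n2_lat, n2_amplitude=n2_amp)


#: Standard CAP input-output grid: levels (dB SPL) x frequencies (kHz)
CAP_LEVELS_DB = (30, 40, 50, 60, 70, 80, 90)
CAP_FREQS_KHZ = (2, 4, 8, 12, 16, 20)


def cap_io_function(features: dict) -> pd.DataFrame:
    """Tidy N1-amplitude table over the (level, frequency) stimulus grid.

    ``features`` maps (level_db, freq_khz) to a CapFeatures or a bare N1
    amplitude.  Missing cells stay missing (no interpolation); duplicate
    keys cannot occur in a dict, but duplicate rows in a pre-built list are
    rejected.
    """
    rows = []
    seen = set()
    for key, feat in features.items():
        level, freq = key
        if (level, freq) in seen:
            raise ValueError(f"duplicate cell {key}")
        seen.add((level, freq))
        amp = feat.n1_amplitude if isinstance(feat, CapFeatures) else float(feat)
        lat = feat.n1_latency_ms if isinstance(feat, CapFeatures) else np.nan
        rows.append({"level_db": level, "freq_khz": freq,
                     "n1_amp_uV": amp, "n1_latency_ms": lat})
    df = pd.DataFrame(rows).sort_values(["freq_khz", "level_db"]).reset_index(drop=True)
    return df
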