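# Methods

`bundlemotion` implements the measurement computations used to characterize
outer-hair-cell stereocilia function in isolated cochlear preparations:
stroboscopic reconstruction of sound-evoked bundle motion from slow confocal
raster scans, optical-flow trajectory extraction, electromotility estimation
from current-polarity-split images, FRAP kinetics, cochlear microphonic (CM)
tuning curves, compound action potential (CAP) feature extraction,
immunofluorescence quantification, and the associated group statistics.
Because no raw imaging or electrophysiology data are publicly deposited for
this kind of experiment, every analysis stage is exercised on synthetic
acquisitions with planted ground truth; this note records the models, the
defaults, and what the synthetic data do and do not emulate.

## Phase-stamped stroboscopic imaging

A confocal raster scan is orders of magnitude slower than an acoustic
stimulus at 180–220 Hz, so a single frame smears many stimulus cycles.  The
key observation is that the acquisition time of pixel (k, r, c) in a
unidirectional forward raster is exactly

    t(k, r, c) = k·T_frame + r·T_line + c·T_dwell,

so every pixel sample carries a known stimulus phase φ = (2πft + φ₀) mod 2π.
Accumulating the 37 frames of a series, each pixel's intensity is a sampled
periodic function of φ, which we fit by ordinary least squares to a Fourier
series

    I(φ) = a₀ + Σ_{n≤N} (aₙ cos nφ + bₙ sin nφ),     N = 2 by default.

Evaluating the fitted series at 12 equally spaced phases renders an
artifact-free movie of one stimulus cycle.  Two harmonics capture the
leading nonlinearity of intensity-vs-displacement at subpixel to ~1.5 px
motion amplitudes; the harmonic order is a parameter.  Pixels whose phase
samples occupy fewer than 8 of 12 equal phase bins (or with fewer than
2N + 3 samples) are flagged invalid instead of fitted — this guards against
stimulus frequencies commensurate with the scan timing, which freeze every
pixel at a few phases.  Invalid pixels are rendered at the a₀ of their
nearest valid neighbour and stay flagged.

Defaults: 64×64 px frames, dwell 10 µs, line time 1 ms, frame interval
40/37 s (37 frames ≈ 40 s per series), 100 nm/px.  The frame count and
series duration reflect the experimental protocol; the dwell and line times
are plausible confocal values chosen to satisfy the raster-timing
inequalities and are *not* hardware values from any specific instrument.
The raster is modelled as unidirectional with no flyback; a bidirectional
flag exists but is off by default because the scanner mode of the original
recordings is not documented.

For square-wave current stimuli (electromotility at 5 Hz, ±10 µA) frames
are not Fourier-fitted: each pixel sample is assigned to the positive or
negative half-cycle of the square wave by its own acquisition time
(half-open intervals — a sample exactly at a transition belongs to the
polarity that starts there), and the two polarity-mean images are compared.
At the default timing the 5 Hz square wave is incommensurate with the frame
interval, so both polarities are populated at every pixel within one
series.

## Motion measurement

Dense subpixel displacements of each rendered phase frame are estimated
relative to the cycle-mean image with an iterative Lucas–Kanade scheme:
windowed structure-tensor normal equations (Gaussian window σ = 2 px),
cubic-spline warping between iterations, at most 20 iterations, convergence
at 10⁻³ px.  The cycle mean is used as the reference so that errors do not
accumulate around the cycle and the mean displacement over phases is ≈ 0 by
construction.  Pixels whose smaller structure-tensor eigenvalue is below
10⁻³ of the image maximum are flagged untextured and excluded.  Frames are
Gaussian-smoothed (σ = 2 px, matching the window) before flow; with weaker
smoothing, frame noise dilutes the image gradients and measurably
attenuates recovered amplitudes.

Point trajectories are the mean of per-pixel trajectories over a 3×3
(default) or 5×5 kernel around the base and tip landmarks, converted to nm.
The scalar **amplitude** of a trajectory is defined as the magnitude of the
fundamental Fourier component of the trajectory projected on its principal
axis.  For x(φ) = A sin φ this returns A, and for a circular trajectory of
radius A it also returns A.  This is *not* half the peak-to-peak excursion;
the fundamental-component definition is robust to per-phase noise, and
recovery tests plant and recover under the same definition.  **Deflection**
is the per-phase vector difference tip − base, the stimulus actually seen
by the transduction channels; its amplitude uses the same definition.

Electromotility is reported as the magnitude of the rigid subpixel shift
between the positive- and negative-polarity mean images, estimated by
upsampled cross-correlation (upsampling factor 200) with spectral whitening
disabled — on these smooth, low-texture images, whitened phase correlation
amplifies noise, while plain cross-correlation recovers planted steps
essentially exactly.  A dense cyclic flow is not meaningful for a
two-image pair.

Known bias: ROI averaging, pre-flow smoothing, and harmonic truncation each
average the motion field over a small spatial neighbourhood.  Where motion
varies along the bundle axis this pulls tip estimates slightly toward the
interior (and base estimates slightly outward), giving a systematic ≈ 3%
underestimate of deflection amplitude at the default operating point; this
is within the 5% recovery band and is inherent to window-based flow on a
spatially graded motion field.

## Synthetic acquisitions

`make_bundle_scene` builds a band-limited template: a bright ridge running
between base and tip landmarks (transverse σ = 3 px) overlaid with
low-pass-filtered speckle (σ = 1.5 px) so flow has texture, smoothed once
more at σ = 1 px.  `simulate_scan` displaces the template under the planted
motion law — base and tip each sinusoidal with their own amplitude, phase,
and direction; interior pixels linearly interpolated along the bundle axis
(the base and tip trajectories are the two constrained quantities; the
interior is unconstrained, and a linear blend is the simplest consistent
choice) — and samples every pixel at its own raster time by cubic
interpolation, adding Gaussian noise truncated at zero (Poisson photon
noise is available but off by default).  Planted amplitudes above 25% of
the image width are rejected because the template would leave interpolation
support.

The generator emulates: raster phase stamping, subpixel periodic motion
with a base→tip gradient, square-wave electromotility, shot-to-shot
Gaussian noise.  It does not emulate: optics (no PSF beyond band-limiting),
focus drift, slow preparation drift across a series, dye bleaching during
acquisition, or 3-D motion components.  Passing recovery tests therefore
demonstrate the correctness of the measurement chain, not robustness to
every nuisance of live-preparation imaging.

Default planted values sit at the pre-injection operating points of the
drug experiments the pipeline is designed for: 98 nm base motion, 90 nm tip
motion, 48 nm deflection, 101 nm electromotility step, CM peak 124 µV,
FRAP τ½ 22 s.  Synthetic noise for recovery tests is set to SNR 20
(noise sd = scene intensity sd / 20).

## FRAP

Traces are 10 baseline samples followed by 30 recovery samples at 1 or 3 s
intervals.  Normalization divides the whole trace by the pre-bleach
baseline mean.  The post-bleach samples are fitted by nonlinear least
squares to the one-phase association model

    F(t) = F_plateau − (F_plateau − F_post)·e^(−kt),   τ½ = ln 2 / k,

with t = 0 at the first post-bleach sample.  (The vendor name "one-phase
decay" for this increasing recovery is retained in some reports; the
association form above is what the data follow.)  Starting values: F_post
from the first post-bleach sample, F_plateau from the mean of the last
three samples, k from a log-linear regression of (F_plateau − F); these are
standard robust starts.  A flat post-bleach trace leaves k unidentifiable
and is reported through `converged = False` with a diagnostic message, not
an exception.  The fit is performed on the mean ROI intensity trace, not
per pixel, matching the single-spot bleaching protocol.  No correction for
bleaching during acquisition is applied (experiments minimize laser power
instead); this is a documented limitation.

Precision note: with noise sd 5% of the plateau, 30 samples at 3 s
intervals, the Cramér–Rao bound for τ½ = 22 s implies a median absolute
relative error ≈ 12%; the fitter operates at that bound.  The *median* of
recovered τ½ over replicates is within a few percent of the planted value
(small bias), which is the calibration the test suite asserts.

## Electrophysiology

**CM tuning curves.**  Tone bursts at 60 dB SPL, 60–820 Hz, sampled at
10 kHz, with 1 ms raised-cosine (Hanning) gates.  The analysis window is
the central span of the burst containing an integer number of stimulus
cycles and excluding the ramps, so the single-sided DFT amplitude at the
bin nearest f₀ returns a pure sinusoid's amplitude exactly (no leakage
correction needed; nearest-bin vs interpolated peak is moot with
integer-cycle windows).  The tuning curve's maximum is the peak amplitude
and its argmax the best frequency (ties resolve to the lowest frequency).
The synthetic tuning grid spans 9 frequencies with a log-frequency Gaussian
shape peaking at 220 Hz.

**CAP.**  Epochs are averaged on their markers first, then a 4th-order
Butterworth band-pass (3 Hz–3 kHz, from the 3–5 Hz / 3–5 kHz hardware
ranges) is applied forward-backward (zero phase) to the average.  Averaging
and linear filtering commute for stationary epochs; filtering the short
average avoids smearing the slow high-pass edge transient of the long raw
trace across epochs.  Amplifier gain (10,000×) is metadata and is never
applied to sample values.  N1 is the first local minimum below baseline in
the 0.5–4 ms search window, N2 the next one; amplitudes are
baseline-to-trough magnitudes (baseline = pre-window mean; the N1–P1
peak-to-peak convention is *not* used), and latencies are refined to
subsample precision by 3-point parabolic interpolation.  Synthetic CAP
epochs are two Gaussian troughs (width 0.3 ms — the waveform morphology is
a modelling choice; only the N1/N2 features are constrained) at 100 kHz,
10 ms epochs, 200 repetitions.  Input–output functions tabulate N1
amplitude over the 7-level × 6-frequency stimulus grid with no
interpolation across missing cells.  Stimulus metadata carries both nominal
and attenuation-corrected SPL; the code never silently re-corrects.

**Drug time courses** are normalized to the pre-injection mean with the
injection at t = 0, mirroring the before/after imaging protocol (2 baseline
sets, 3–4 sets after injection at 5-min intervals).

## Immunofluorescence quantification

Background is the pooled mean of user-chosen signal-free ROIs (≥ 25 px
each), subtracted as a scalar with negatives clipped.  Per-bundle mean
intensities (bundles outlined manually as masks — no segmentation is
implemented or claimed) are normalized to the preparation's global average,
so normalized values average exactly 1 and renormalization is idempotent.
Axial profiles average intensity in a 3 px-wide band along the base→tip
axis, resampled at 50 equally spaced stations and normalized to the profile
maximum (other normalizations are options); multi-bundle averages report
mean ± s.e.m. and the bundle count.  Channel independence is an OLS
regression of channel-2 on channel-1 pixel intensities with r²; the slope
direction is configurable since r² is symmetric.  Under a planted
bleed-through fraction β the slope estimates β, which is the sensitivity
check that "no relationship" is a detectable claim.

## Statistics

Normality screening uses the Kolmogorov–Smirnov test with sample-estimated
mean and sd and the Lilliefors correction (the uncorrected KS against the
fitted normal is an option, with conservative p-values).  Pre/post
comparisons are two-tailed paired t-tests; treated-vs-vehicle comparisons
are two-tailed unpaired t-tests with Welch's correction.  Identical paired
samples return t = 0, p = 1 rather than NaN.  Star annotations: p < 0.05
(*), < 0.01 (**), < 0.001 (***), < 0.0001 (****).  Grids of level ×
frequency measurements use two-way fixed-effects ANOVA (type-II sums of
squares) with Bonferroni-multiplied pairwise treatment comparisons within
each level of the second factor, capped at 1.  Repeated 5-min time points
are treated as fixed effects, not repeated measures — a documented
simplification.

## Problem sizes and determinism

All recovery computations run on 64×64 px, 37-frame series (a full
simulate → reconstruct → flow chain takes well under a second), 200-seed
FRAP replicate batches, and 10⁴-replicate null calibrations for the t-test
suite.  Every generator is a pure function of its parameters and a seed;
the acceptance script derives independent per-target sub-seeds from a
single `--seed` via `numpy.random.SeedSequence`.

## Known limitations

- No drift correction across a series; non-periodic motion is out of scope.
- The interior displacement interpolation is linear along the bundle axis;
  real bundles may flex nonlinearly.
- The ≈3% deflection underestimate from spatial averaging (above).
- FRAP assumes a single diffusing component; anomalous or two-component
  recovery is out of scope, and τ½ is not converted to a diffusion
  coefficient.
- No CAP threshold estimation or audiogram modelling.
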