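"""Stroboscopic reconstruction: per-pixel time/phase bookkeeping and the
Fourier-series fit, checked against closed forms and exhaustive oracles."""

import numpy as np
import pytest

from bundlemotion.datatypes import ScanConfig, StimulusSpec, TimedStack
from bundlemotion.phase_recon import (
    TimeMap,
    fit_fourier_series,
    pixel_times,
    render_phase_stack,
    split_by_polarity,
)


def brute_force_times(scan):
    """Independent enumeration of the forward raster order."""
    t = np.zeros((scan.n_frames, scan.image_height, scan.image_width))
    for k in range(scan.n_frames):
        for r in range(scan.image_height):
            for c in range(scan.image_width):
                t[k, r, c] = (k * scan.frame_interval + r * scan.line_time
                              + c * scan.pixel_dwell)
    return t


def stack_from_phases(phi, intensity_fn, scan=None, frequency=1.0 / (2 * np.pi)):
    """TimedStack whose pixels sample intensity_fn at prescribed phases.

    Uses t = phi / (2*pi*frequency) so the stimulus phase of frame j is
    exactly phi[j]; the scan's nominal raster timing is bypassed through an
    explicit TimeMap.
    """
    n, h, w = phi.shape
    if scan is None:
        scan = ScanConfig(image_height=h, image_width=w, pixel_dwell=1e-9,
                          line_time=h * 1e-9 + 1e-9, frame_interval=1.0,
                          n_frames=n, nm_per_pixel=100.0)
    t = phi / (2 * np.pi * frequency)
    tm = TimeMap(t=t, scan=scan)
    frames = intensity_fn(phi)
    stim = StimulusSpec(kind="tone", frequency=frequency, level=80.0)
    return TimedStack(frames=frames, scan=scan, stimulus=stim), tm


class TestPixelTimes:
    def test_origin_pixel_time_is_zero(self, scan):
        assert pixel_times(scan).t[0, 0, 0] == 0.0

    def test_matches_exhaustive_raster_enumeration(self):
        scan = ScanConfig(image_height=4, image_width=3, pixel_dwell=2e-6,
                          line_time=1e-4, frame_interval=0.01, n_frames=3)
        np.testing.assert_allclose(pixel_times(scan).t, brute_force_times(scan),
                                   rtol=0, atol=0)

    def test_phase_periodicity(self, scan):
        tm = pixel_times(scan)
        phi0 = 0.7
        # one full stimulus period later the phase returns to phi0
        phase = np.mod(2 * np.pi * 220.0 * (1.0 / 220.0) + phi0, 2 * np.pi)
        assert phase == pytest.approx(phi0)
        assert np.all(tm.phase(220.0) >= 0)
        assert np.all(tm.phase(220.0) < 2 * np.pi)

    def test_bidirectional_reverses_odd_rows(self):
        scan = ScanConfig(image_height=4, image_width=3, pixel_dwell=2e-6,
                          line_time=1e-4, frame_interval=0.01, n_frames=1)
        t = pixel_times(scan, bidirectional=True).t[0]
        assert np.all(np.diff(t[0]) > 0)  # even row forward
        assert np.all(np.diff(t[1]) < 0)  # odd row reversed


class TestFourierFit:
    def test_recovers_closed_form_cosine(self):
        # 37 phases per pixel, spread as in the real raster
        rng = np.random.default_rng(0)
        phi = np.mod(np.cumsum(rng.uniform(0.3, 1.2, size=(37, 4, 4)), axis=0),
                     2 * np.pi)
        stack, tm = stack_from_phases(phi, lambda p: 5.0 + 2.0 * np.cos(p))
        cf = fit_fourier_series(stack, timemap=tm, n_harm=2)
        assert cf.valid.all()
        np.testing.assert_allclose(cf.a0, 5.0, atol=1e-6)
        np.testing.assert_allclose(cf.an[0], 2.0, atol=1e-6)
        np.testing.assert_allclose(cf.bn[0], 0.0, atol=1e-6)
        np.testing.assert_allclose(cf.an[1], 0.0, atol=1e-6)
        np.testing.assert_allclose(cf.bn[1], 0.0, atol=1e-6)

    def test_constant_pixels_give_a0_only(self, scan, tone):
        frames = np.full((scan.n_frames, 64, 64), 42.0)
        stack = TimedStack(frames=frames, scan=scan, stimulus=tone)
        cf = fit_fourier_series(stack)
        np.testing.assert_allclose(cf.a0[cf.valid], 42.0, atol=1e-9)
        np.testing.assert_allclose(cf.an[:, cf.valid], 0.0, atol=1e-9)
        np.testing.assert_allclose(cf.bn[:, cf.valid], 0.0, atol=1e-9)

    def test_commensurate_stimulus_fails_coverage(self, scan):
        """Stimulus period equal to the frame interval clusters all samples
        of a pixel into one phase bin, so no pixel can be fitted."""
        f_comm = 37.0 / 40.0  # exactly one cycle per frame interval
        stim = StimulusSpec(kind="tone", frequency=f_comm, level=80.0)
        frames = np.ones((scan.n_frames, 64, 64))
        stack = TimedStack(frames=frames, scan=scan, stimulus=stim)
        with pytest.raises(ValueError, match="commensurate"):
            fit_fourier_series(stack)

    def test_linearity_in_intensity(self, scan, tone, scene):
        from bundlemotion.synthgen import simulate_scan
        from conftest import make_truth

        stack = simulate_scan(scene, make_truth(), scan, tone, noise_sd=0.0)
        cf1 = fit_fourier_series(stack)
        stack3 = TimedStack(frames=3.0 * stack.frames, scan=scan, stimulus=tone)
        cf3 = fit_fourier_series(stack3)
        np.testing.assert_allclose(cf3.a0, 3.0 * cf1.a0, rtol=1e-9)
        np.testing.assert_allclose(cf3.an, 3.0 * cf1.an, rtol=1e-9, atol=1e-9)
        ps1 = render_phase_stack(cf1)
        ps3 = render_phase_stack(cf3)
        np.testing.assert_allclose(ps3.frames, 3.0 * ps1.frames, rtol=1e-9)


class TestRenderPhaseStack:
    def test_default_is_12_equally_spaced_phases(self, scan, tone):
        frames = np.full((scan.n_frames, 64, 64), 7.0)
        cf = fit_fourier_series(TimedStack(frames=frames, scan=scan, stimulus=tone))
        ps = render_phase_stack(cf)
        assert ps.n_phases == 12
        np.testing.assert_allclose(ps.phases,
                                   2 * np.pi * np.arange(12) / 12)

    def test_a0_only_renders_identical_frames(self, scan, tone):
        frames = np.full((scan.n_frames, 64, 64), 7.0)
        cf = fit_fourier_series(TimedStack(frames=frames, scan=scan, stimulus=tone))
        ps = render_phase_stack(cf)
        for j in range(12):
            np.testing.assert_allclose(ps.frames[j], 7.0, atol=1e-9)

    def test_phase_zero_is_a0_plus_sum_of_cosines(self):
        rng = np.random.default_rng(1)
        phi = np.mod(np.cumsum(rng.uniform(0.3, 1.2, size=(37, 3, 3)), axis=0),
                     2 * np.pi)

        def trig(p):
            return 4.0 + 1.5 * np.cos(p) - 0.5 * np.sin(p) + 0.25 * np.cos(2 * p)

        stack, tm = stack_from_phases(phi, trig)
        cf = fit_fourier_series(stack, timemap=tm)
        ps = render_phase_stack(cf)
        expected = cf.a0 + cf.an.sum(axis=0)  # cos(n*0) = 1, sin = 0
        np.testing.assert_allclose(ps.frames[0], expected, atol=1e-9)

    def test_too_few_phases_rejected(self, scan, tone):
        frames = np.full((scan.n_frames, 64, 64), 7.0)
        cf = fit_fourier_series(TimedStack(frames=frames, scan=scan, stimulus=tone))
        with pytest.raises(ValueError):
            render_phase_stack(cf, n_phases=2)

    def test_exact_for_trigonometric_polynomial_stacks(self):
        """Noiseless trig-polynomial intensities are reconstructed with
        relative RMS error < 1e-6 at the rendered phases."""
        rng = np.random.default_rng(2)
        phi = np.mod(np.cumsum(rng.uniform(0.3, 1.2, size=(37, 6, 6)), axis=0),
                     2 * np.pi)
        a0 = rng.uniform(5, 10, (6, 6))
        a1 = rng.normal(0, 1, (6, 6))
        b1 = rng.normal(0, 1, (6, 6))
        a2 = rng.normal(0, 0.3, (6, 6))
        b2 = rng.normal(0, 0.3, (6, 6))

        def trig(p):
            return (a0 + a1 * np.cos(p) + b1 * np.sin(p)
                    + a2 * np.cos(2 * p) + b2 * np.sin(2 * p))

        stack, tm = stack_from_phases(phi, trig)
        cf = fit_fourier_series(stack, timemap=tm, n_harm=2)
        ps = render_phase_stack(cf, n_phases=12)
        truth = np.stack([trig(np.full((6, 6), p)) for p in ps.phases])
        rel_rms = np.sqrt(np.mean((ps.frames - truth) ** 2)) / np.sqrt(
            np.mean(truth ** 2))
        assert rel_rms < 1e-6

    def test_refitting_rendered_stack_is_idempotent(self):
        rng = np.random.default_rng(3)
        phi = np.mod(np.cumsum(rng.uniform(0.3, 1.2, size=(37, 4, 4)), axis=0),
                     2 * np.pi)

        def trig(p):
            return 6.0 + np.cos(p) + 0.4 * np.sin(2 * p)

        stack, tm = stack_from_phases(phi, trig)
        cf = fit_fourier_series(stack, timemap=tm)
        ps = render_phase_stack(cf, n_phases=12)
        # refit using the rendered phases as design points
        phi2 = np.broadcast_to(ps.phases[:, None, None], ps.frames.shape).copy()
        stack2, tm2 = stack_from_phases(phi2, lambda p: ps.frames)
        cf2 = fit_fourier_series(stack2, timemap=tm2,
                                 min_occupied_bins=8)
        np.testing.assert_allclose(cf2.a0, cf.a0, atol=1e-9)
        np.testing.assert_allclose(cf2.an, cf.an, atol=1e-9)
        np.testing.assert_allclose(cf2.bn, cf.bn, atol=1e-9)


class TestPolaritySplit:
    def test_zero_step_gives_equal_images(self, scene, scan, square_current):
        from bundlemotion.synthgen import simulate_scan
        from conftest import make_truth

        truth = make_truth(base_amplitude=0.0, tip_amplitude=0.0, em_step=0.0)
        stack = simulate_scan(scene, truth, scan, square_current, noise_sd=0.0)
        pair = split_by_polarity(stack)
        np.testing.assert_allclose(pair.positive, pair.negative, atol=1e-9)

    def test_both_polarities_populated_with_incommensurate_timing(
            self, scene, scan, square_current):
        """At 5 Hz with a 40/37 s frame interval every pixel samples both
        half-cycles over 37 frames."""
        from bundlemotion.synthgen import simulate_scan
        from conftest import make_truth

        truth = make_truth(base_amplitude=0.0, tip_amplitude=0.0, em_step=50.0)
        stack = simulate_scan(scene, truth, scan, square_current, noise_sd=0.0)
        pair = split_by_polarity(stack)
        assert pair.valid.all()
        assert pair.n_positive.min() >= 1
        assert pair.n_negative.min() >= 1
        assert np.all(pair.n_positive + pair.n_negative == scan.n_frames)

    def test_counts_match_exhaustive_time_enumeration(self, square_current):
        scan = ScanConfig(image_height=4, image_width=3, pixel_dwell=2e-3,
                          line_time=8e-3, frame_interval=0.04, n_frames=5)
        frames = np.ones((5, 4, 3))
        stim = square_current
        stack = TimedStack(frames=frames, scan=scan, stimulus=stim)
        pair = split_by_polarity(stack)
        # brute-force: enumerate every pixel time and classify by half-cycle
        for r in range(4):
            for c in range(3):
                n_pos = 0
                for k in range(5):
                    t = k * 0.04 + r * 8e-3 + c * 2e-3
                    if (t * 5.0) % 1.0 < 0.5:
                        n_pos += 1
                assert pair.n_positive[r, c] == n_pos

    def test_requires_square_wave_stimulus(self, scan, tone):
        frames = np.ones((scan.n_frames, 64, 64))
        stack = TimedStack(frames=frames, scan=scan, stimulus=tone)
        with pytest.raises(ValueError, match="square_current"):
            split_by_polarity(stack)
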