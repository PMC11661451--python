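"""Z-score pipeline: registration, scoring, segmentation, figures of merit."""

import numpy as np
import pytest
from scipy import ndimage

from electroscatter.circuit import Pulse, StimulusProtocol
from electroscatter.imaging import (
    ElectroOpticSummary,
    ImageSequence,
    RoiSpec,
    ZScoreTrace,
    characterize,
    extract_antenna_trace,
    fit_time_constant,
    pixel_zscores,
    plateau_response,
    register_translation,
    summarize_boxchart,
)


def _textured_frame(rng, shape=(64, 64)):
    """A speckle-like frame with enough structure for phase correlation."""
    img = rng.uniform(100, 200, size=shape)
    return ndimage.gaussian_filter(img, 1.0) * 10


class TestRegistration:
    def test_aligned_stack_reports_zero_shifts(self, rng):
        frame = _textured_frame(rng)
        seq = ImageSequence(np.stack([frame] * 5), 100.0, 0.325)
        registered, shifts = register_translation(seq)
        assert np.all(np.abs(shifts) < 0.05)
        assert np.allclose(registered.frames, seq.frames, rtol=1e-6)

    def test_integer_shift_recovered_exactly(self, rng):
        frame = _textured_frame(rng)
        shifted = np.roll(np.roll(frame, 3, axis=0), -2, axis=1)
        seq = ImageSequence(np.stack([frame, shifted]), 100.0, 0.325)
        _, shifts = register_translation(seq)
        assert shifts[1] == pytest.approx([-3.0, 2.0], abs=1e-6)

    def test_subpixel_shift_recovered(self, rng):
        frame = _textured_frame(rng)
        shifted = ndimage.shift(frame, (0.3, -0.3), order=3, mode="nearest")
        seq = ImageSequence(np.stack([frame, shifted]), 100.0, 0.325)
        _, shifts = register_translation(seq)
        assert shifts[1] == pytest.approx([-0.3, 0.3], abs=0.1)

    def test_featureless_frame_rejected(self):
        seq = ImageSequence(np.ones((3, 32, 32)), 100.0, 0.325)
        with pytest.raises(ValueError):
            register_translation(seq)


class TestPixelZScores:
    def test_baseline_is_normalized(self, rng):
        frames = rng.poisson(500.0, size=(100, 16, 16)).astype(float)
        seq = ImageSequence(frames, 200.0, 0.325)
        z, valid = pixel_zscores(seq, (0, 100))
        assert valid.all()
        assert np.abs(z[:100].mean(axis=0)).max() < 1e-4
        assert np.abs(z[:100].std(axis=0) - 1).max() < 1e-4

    def test_constant_pixel_flagged_invalid(self, rng):
        frames = rng.poisson(500.0, size=(50, 8, 8)).astype(float)
        frames[:, 3, 4] = 123.0
        seq = ImageSequence(frames, 200.0, 0.325)
        z, valid = pixel_zscores(seq, (0, 50))
        assert not valid[3, 4]
        assert np.all(z[:, 3, 4] == 0)
        assert valid.sum() == 63

    def test_hand_worked_toy_pixel(self):
        baseline = np.array([10.0, 12.0, 11.0, 10.0, 12.0])
        frames = np.concatenate([np.tile(baseline, 2), [20.0]]).reshape(-1, 1, 1)
        frames = np.tile(frames, (1, 2, 2))
        frames[:, 1, 1] += 1.0  # break exact symmetry elsewhere
        seq = ImageSequence(frames, 100.0, 0.325)
        z, valid = pixel_zscores(seq, (0, 10))
        mu, sd = np.mean(np.tile(baseline, 2)), np.std(np.tile(baseline, 2))
        assert z[10, 0, 0] == pytest.approx((20.0 - mu) / sd, rel=1e-6)

    def test_short_baseline_rejected(self, rng):
        seq = ImageSequence(rng.poisson(100.0, (20, 8, 8)).astype(float), 100.0, 0.3)
        with pytest.raises(ValueError):
            pixel_zscores(seq, (0, 5))


class TestTraceExtraction:
    def _zstack_with_spot(self, rng, amplitude, sigma_px=2.0, shape=(40, 40), n=200):
        z = rng.standard_normal((n, *shape))
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        spot = np.exp(-((rr - 20) ** 2 + (cc - 20) ** 2) / (2 * sigma_px**2))
        z[n // 2 :] += amplitude * spot
        return z.astype(np.float32)

    def test_single_responsive_pixel(self, rng):
        z = rng.standard_normal((100, 20, 20)).astype(np.float32) * 0.01
        z[50:, 10, 10] += 8.0
        trace = extract_antenna_trace(z, RoiSpec((10, 10), 5), 100.0, (50, 100))
        assert trace.pixel_mask.sum() == 1
        assert np.allclose(trace.z, z[:, 10, 10])

    def test_no_responsive_pixels_is_explicit(self, rng):
        z = (0.01 * rng.standard_normal((100, 20, 20))).astype(np.float32)
        trace = extract_antenna_trace(z, RoiSpec((10, 10), 5), 100.0, (50, 100))
        assert not trace.has_responsive_pixels

    def test_gaussian_spot_mask_and_amplitude(self, rng):
        """Mask concentric with the spot; amplitude within 10% of programmed."""
        amp = 20.0
        z = self._zstack_with_spot(rng, amp)
        trace = extract_antenna_trace(z, RoiSpec((20, 20), 15), 100.0, (100, 200))
        rows, cols = np.nonzero(trace.pixel_mask)
        assert rows.mean() == pytest.approx(20, abs=0.5)
        assert cols.mean() == pytest.approx(20, abs=0.5)
        # programmed mean over the mask
        rr, cc = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        spot = np.exp(-((rr - 20) ** 2 + (cc - 20) ** 2) / 8.0)
        programmed = amp * spot[trace.pixel_mask].mean()
        measured = trace.z[100:].mean()
        assert measured == pytest.approx(programmed, rel=0.10)

    def test_roi_outside_frame_rejected(self, rng):
        z = rng.standard_normal((20, 20, 20)).astype(np.float32)
        with pytest.raises(ValueError):
            extract_antenna_trace(z, RoiSpec((30, 10), 5), 100.0)


class TestCharacterize:
    def test_definitional_lod(self, rng):
        noise_trace = 0.5 * rng.standard_normal(2000)
        noise_trace = noise_trace / noise_trace.std() * 0.5  # exact SD 0.5
        responses = {-(v / 1e3): 0.2 * v for v in (20, 60, 100)}
        s = characterize(responses, noise_trace)
        assert s.noise == pytest.approx(0.5)
        assert s.sensitivity == pytest.approx(0.2)
        assert s.lod == pytest.approx(0.5 / 0.2)  # 2.5 mV
        assert s.lod == s.noise / s.sensitivity  # identity holds exactly

    def test_snr_definition(self, rng):
        noise_trace = rng.standard_normal(500)
        noise_trace = noise_trace / noise_trace.std()  # noise = 1
        responses = {-0.02: 9.6, -0.06: 28.8, -0.1: 48.0}  # plateau = 48 * noise
        s = characterize(responses, noise_trace)
        assert s.snr == pytest.approx(48.0, rel=1e-6)

    def test_exact_linear_response_recovers_slope(self, rng):
        amplitudes = [-(v / 1e3) for v in range(10, 101, 10)]
        responses = {a: 0.3 * abs(a) * 1e3 for a in amplitudes}
        s = characterize(responses, rng.standard_normal(100))
        assert s.sensitivity == pytest.approx(0.3, rel=1e-12)

    def test_nonpositive_sensitivity_flags_lod(self, rng):
        responses = {-0.02: 1.0, -0.06: 0.5, -0.1: 0.1}
        s = characterize(responses, rng.standard_normal(100))
        assert s.sensitivity < 0
        assert s.lod is None

    def test_requires_three_amplitudes(self, rng):
        with pytest.raises(ValueError):
            characterize({-0.1: 5.0, -0.05: 2.5}, rng.standard_normal(100))


class TestTimeConstantFit:
    def test_noiseless_round_trip(self):
        t = np.arange(0, 0.4, 1 / 2000.0)
        y = 3.0 * (1 - np.exp(-np.clip(t - 0.05, 0, None) / 34.7e-3))
        tau = fit_time_constant((t, y), onset=0.05)
        assert tau == pytest.approx(34.7, rel=0.01)

    def test_instantaneous_step_bounded_by_frame_period(self):
        t = np.arange(0, 0.1, 1 / 2000.0)
        y = np.where(t >= 0.02, 5.0, 0.0)
        tau = fit_time_constant((t, y), onset=0.02)
        assert tau <= 1e3 / 2000.0 + 1e-6

    def test_monte_carlo_recovery_under_noise(self):
        """Median error < 10% with noise SD at 10% of amplitude, 50 seeds."""
        errs = []
        t = np.arange(0, 0.4, 1 / 2000.0)
        clean = 1.0 * (1 - np.exp(-t / 34.7e-3))
        for seed in range(50):
            rng = np.random.default_rng(seed)
            tau = fit_time_constant((t, clean + 0.1 * rng.standard_normal(t.size)), 0.0)
            errs.append(abs(tau - 34.7) / 34.7)
        assert np.median(errs) < 0.10


class TestRegistrationInvariance:
    def test_jittered_then_registered_matches_jitter_free(self):
        """Rigid jitter, once compensated, leaves the figures of merit intact."""
        from electroscatter.circuit import CircuitParams, Pulse, StimulusProtocol
        from electroscatter.electro_optic import SigmoidTransfer
        from electroscatter.imaging import characterize_stack, register_translation
        from electroscatter.synthetic import ArrayLayout, NoiseModel, render_sequence

        circuit = CircuitParams(1e4, 9.9e5, 6e-9)
        transfer = SigmoidTransfer(2e4, 6e5, -0.35, 0.12)
        pulses = tuple(Pulse(a, 1.2 + i * 1.4, 1.0) for i, a in enumerate((-0.04, -0.07, -0.1)))
        protocol = StimulusProtocol(-0.35, pulses, 1.2 + 1.4 * 3, 200.0)
        layout = ArrayLayout(n_rows=4, n_cols=4, peak_counts=1200.0)
        base_noise = NoiseModel(speckle_drift_sd=0.2, speckle_corr=0.995)
        jitter_noise = NoiseModel(
            speckle_drift_sd=0.2, speckle_corr=0.995, jitter_sd=0.5
        )
        seq_clean, _ = render_sequence(layout, circuit, transfer, base_noise, protocol, 5)
        seq_jit, _ = render_sequence(layout, circuit, transfer, jitter_noise, protocol, 5)
        seq_reg, shifts = register_translation(seq_jit)
        assert np.abs(shifts).max() > 0.2  # jitter was real and detected

        radius = layout.pitch_px / 2 - 1
        clean = characterize_stack(seq_clean, layout.centers(), protocol, roi_radius=radius)
        reg = characterize_stack(seq_reg, layout.centers(), protocol, roi_radius=radius)
        sens_clean = np.median([s.sensitivity for s in clean if s])
        sens_reg = np.median([s.sensitivity for s in reg if s])
        assert sens_reg == pytest.approx(sens_clean, rel=0.05)


class TestBoxChart:
    def test_hand_computed_octet(self):
        b = summarize_boxchart(list(range(1, 9)))
        assert b.median == 4.5
        # numpy linear interpolation quartiles of 1..8
        assert b.q1 == pytest.approx(2.75)
        assert b.q3 == pytest.approx(6.25)
        assert b.whisker_lo == 1 and b.whisker_hi == 8
        assert b.outliers == ()

    def test_all_equal_values(self):
        b = summarize_boxchart([5.0] * 6)
        assert b.median == 5.0 and b.q1 == b.q3 == 5.0
        assert b.outliers == ()

    def test_extreme_value_flagged(self):
        b = summarize_boxchart(list(range(1, 9)) + [100.0])
        assert 100.0 in b.outliers
        assert b.whisker_hi == 8

    def test_requires_four_values(self):
        with pytest.raises(ValueError):
            summarize_boxchart([1.0, 2.0, 3.0])
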