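"""Preprocessing: LED synchronization, dropped-frame interpolation,
dF/F0, clipping, hemodynamic correction, and filtering."""
from __future__ import annotations

import numpy as np
import pytest

from duobrain.core import BLUE, GREEN, AlignmentError, DffStack, RawStack, SyncError
from duobrain.preprocess import (
    DegeneratePixelError,
    clip_extremes,
    compute_dff,
    crop_to_onset,
    detect_led_onset,
    hemodynamic_correct,
    interpolate_dropped_frames,
    preprocess_session,
    smooth_and_bandpass,
)
from duobrain.synthetic import SessionParams, simulate_session


def _stack_from_means(means, fs=28.9, shape=(2, 2)):
    frames = np.ones((len(means),) + shape, dtype=np.float32)
    frames *= np.asarray(means, dtype=np.float32)[:, None, None]
    return RawStack(frames, np.arange(len(means)) / fs, GREEN)


class TestLedOnset:
    def test_step_series_onset_index(self):
        stack = _stack_from_means([1, 1, 1, 100, 100])
        assert detect_led_onset(stack) == 3

    def test_constant_series_raises(self):
        with pytest.raises(SyncError):
            detect_led_onset(_stack_from_means([5, 5, 5, 5]))

    def test_noise_does_not_move_onset(self):
        """Additive noise (SD 1 on a 1 vs 100 step) never shifts the
        detected index — checked by brute force over noise seeds."""
        base = np.array([1.0] * 17 + [100.0] * 33)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            stack = _stack_from_means(base + rng.normal(0, 1, len(base)))
            assert detect_led_onset(stack) == 17

    def test_crop_resets_clock(self):
        stack = _stack_from_means([1, 1, 1, 100, 100, 100])
        cropped = crop_to_onset(stack)
        assert cropped.shape[0] == 3
        assert cropped.timestamps[0] == 0.0


class TestInterpolation:
    def test_no_gaps_is_identity(self):
        fs = 10.0
        frames = np.arange(40, dtype=np.float32).reshape(10, 2, 2)
        stack = RawStack(frames, np.arange(10) / fs, GREEN)
        out = interpolate_dropped_frames(stack, fs)
        assert np.array_equal(out.frames, frames)
        assert np.allclose(out.timestamps, stack.timestamps)

    def test_single_gap_linear_midpoint(self):
        fs = 10.0
        frames = np.full((3, 2, 2), [[10.0]], dtype=np.float32)
        frames[1] = 20.0
        frames[2] = 20.0
        # timestamps 0, 0.2, 0.3: one frame missing at 0.1
        stack = RawStack(frames, np.array([0.0, 0.2, 0.3]), GREEN)
        out = interpolate_dropped_frames(stack, fs)
        assert out.frames.shape[0] == 4
        assert np.allclose(out.frames[1], 15.0)
        assert np.allclose(out.frames[0], 10.0)
        assert np.allclose(out.frames[2], 20.0)

    def test_double_gap_two_inserted_frames(self):
        fs = 10.0
        frames = np.zeros((2, 1, 1), dtype=np.float32)
        frames[1] = 30.0
        stack = RawStack(frames, np.array([0.0, 0.3]), GREEN)
        out = interpolate_dropped_frames(stack, fs)
        assert out.frames.shape[0] == 4
        assert np.allclose(out.frames[:, 0, 0], [0.0, 10.0, 20.0, 30.0])


class TestDff:
    def test_constant_stack_is_zero(self):
        frames = np.full((5, 3, 3), 7.0, dtype=np.float32)
        stack = RawStack(frames, np.arange(5) / 10.0, GREEN)
        dff = compute_dff(stack, np.ones((3, 3), bool))
        assert np.allclose(dff.values, 0.0)

    def test_two_sample_closed_form(self):
        frames = np.zeros((2, 1, 1), dtype=np.float32)
        frames[0] = 1.0
        frames[1] = 3.0
        stack = RawStack(frames, np.array([0.0, 0.1]), GREEN)
        dff = compute_dff(stack, np.ones((1, 1), bool))
        assert np.allclose(dff.values[:, 0, 0], [-0.5, 0.5])

    def test_scale_invariance(self, rng):
        frames = rng.uniform(10, 20, (20, 4, 4)).astype(np.float32)
        ts = np.arange(20) / 10.0
        mask = np.ones((4, 4), bool)
        d1 = compute_dff(RawStack(frames, ts, GREEN), mask)
        d2 = compute_dff(RawStack(frames * 3.7, ts, GREEN), mask)
        assert np.allclose(d1.values, d2.values, atol=1e-5)

    def test_nonpositive_baseline_raises_with_pixels(self):
        frames = np.full((4, 2, 2), 5.0, dtype=np.float32)
        frames[:, 1, 1] = 0.0
        stack = RawStack(frames, np.arange(4) / 10.0, GREEN)
        with pytest.raises(DegeneratePixelError) as exc:
            compute_dff(stack, np.ones((2, 2), bool))
        assert [1, 1] in exc.value.pixels.tolist()


class TestClip:
    def _dff(self, series):
        values = np.asarray(series, dtype=np.float32)[:, None, None]
        return DffStack(values, np.ones((1, 1), bool), 10.0, ["dff"])

    def test_gcamp_outlier_moves_to_mean_plus_3p5_sd(self, rng):
        series = np.concatenate([rng.normal(0, 1, 200), [25.0]])
        clipped = clip_extremes(self._dff(series), "gcamp").values[:, 0, 0]
        hi = series.mean() + 3.5 * series.std()
        assert clipped.max() == pytest.approx(hi, rel=1e-5)
        inliers = np.abs(series - series.mean()) < 3.5 * series.std()
        assert np.allclose(clipped[inliers], series[inliers], atol=1e-5)

    def test_reflectance_clips_at_15_percent(self):
        clipped = clip_extremes(
            self._dff([0.4, -0.2, 0.05]), "reflectance"
        ).values[:, 0, 0]
        assert np.allclose(clipped, [0.15, -0.15, 0.05])

    def test_reflectance_idempotent(self):
        once = clip_extremes(self._dff([0.4, -0.2, 0.05]), "reflectance")
        twice = clip_extremes(once, "reflectance")
        assert np.array_equal(once.values, twice.values)

    def test_constant_series_unchanged(self):
        out = clip_extremes(self._dff([0.3] * 10), "gcamp").values
        assert np.allclose(out, 0.3)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            clip_extremes(self._dff([0.0, 0.1]), "both")


class TestHemodynamicCorrect:
    def _pair(self, g, b):
        mask = np.ones((1, 1), bool)
        gd = DffStack(np.asarray(g, np.float32)[:, None, None], mask, 10.0, ["dff"])
        bd = DffStack(np.asarray(b, np.float32)[:, None, None], mask, 10.0, ["dff"])
        return gd, bd

    def test_zero_blue_is_identity(self):
        gd, bd = self._pair([0.05, 0.02], [0.0, 0.0])
        out = hemodynamic_correct(gd, bd)
        assert np.allclose(out.values, gd.values)

    def test_equal_channels_cancel(self):
        gd, bd = self._pair([0.05, 0.02], [0.05, 0.02])
        assert np.allclose(hemodynamic_correct(gd, bd).values, 0.0)

    def test_elementwise_difference(self):
        gd, bd = self._pair([0.05], [0.02])
        assert hemodynamic_correct(gd, bd).values[0, 0, 0] == pytest.approx(0.03)

    def test_shape_mismatch_raises(self):
        gd, _ = self._pair([0.05, 0.02], [0.0, 0.0])
        mask = np.ones((2, 2), bool)
        bd = DffStack(np.zeros((2, 2, 2), np.float32), mask, 10.0, [])
        with pytest.raises(AlignmentError):
            hemodynamic_correct(gd, bd)

    def test_provenance_records_both_parents(self):
        gd, bd = self._pair([0.05, 0.02], [0.01, 0.0])
        bd.provenance.append("clip[reflectance]")
        out = hemodynamic_correct(gd, bd)
        assert any("green-blue" in p for p in out.provenance)
        assert any("reflectance" in p for p in out.provenance)


class TestFiltering:
    def _sine_stack(self, freq_hz, fs=28.9, dur=80.0, shape=(3, 3)):
        t = np.arange(int(dur * fs)) / fs
        vals = np.sin(2 * np.pi * freq_hz * t)[:, None, None] * np.ones(shape)
        return DffStack(
            vals.astype(np.float32), np.ones(shape, bool), fs, ["dff"]
        )

    def test_1hz_amplitude_preserved_within_1_percent(self):
        out = smooth_and_bandpass(self._sine_stack(1.0))
        mid = slice(200, -200)
        a_in = np.sqrt(2) * self._sine_stack(1.0).values[mid, 1, 1].std()
        a_out = np.sqrt(2) * out.values[mid, 1, 1].std()
        assert a_out == pytest.approx(a_in, rel=0.01)

    def test_dc_rejected(self):
        vals = np.full((1000, 3, 3), 0.2, dtype=np.float32)
        dff = DffStack(vals, np.ones((3, 3), bool), 28.9, ["dff"])
        with pytest.warns(UserWarning, match="time constant"):
            out = smooth_and_bandpass(dff)
        assert np.abs(out.values).max() < 1e-4

    def test_dc_shift_invariance(self):
        base = self._sine_stack(0.7)
        shifted = DffStack(
            base.values + 0.3, base.mask, base.fs, list(base.provenance)
        )
        o1 = smooth_and_bandpass(base)
        o2 = smooth_and_bandpass(shifted)
        assert np.allclose(o1.values, o2.values, atol=1e-4)

    def test_spatial_impulse_blurred_to_unit_gaussian(self):
        """The per-frame spatial smoothing of an impulse should match
        the analytic 2-D Gaussian with sigma = 1 px."""
        fs = 28.9
        t = np.arange(int(60 * fs)) / fs
        carrier = np.sin(2 * np.pi * 1.0 * t)
        vals = np.zeros((len(t), 15, 15), dtype=np.float32)
        vals[:, 7, 7] = carrier
        dff = DffStack(vals, np.ones((15, 15), bool), fs, ["dff"])
        out = smooth_and_bandpass(dff)
        peak_frame = out.values[int(7.25 * fs)]  # near a carrier peak
        yy, xx = np.mgrid[0:15, 0:15]
        analytic = np.exp(-((xx - 7) ** 2 + (yy - 7) ** 2) / 2.0)
        a = peak_frame.ravel() / peak_frame.sum()
        b = analytic.ravel() / analytic.sum()
        corr = np.corrcoef(a, b)[0, 1]
        assert corr > 0.999

    def test_low_fs_rejected(self):
        vals = np.zeros((100, 2, 2), dtype=np.float32)
        dff = DffStack(vals, np.ones((2, 2), bool), 20.0, ["dff"])
        with pytest.raises(ValueError, match="band edge"):
            smooth_and_bandpass(dff)


class TestPipeline:
    def test_provenance_order(self, coupled_session):
        _, _, _, processed = coupled_session
        prov = processed["stationary"]["corrected"].provenance
        main_steps = [p for p in prov if not p.startswith("  blue:")]
        assert main_steps[0] == "dff"
        assert main_steps[1].startswith("clip[gcamp]")
        assert main_steps[2].startswith("hemodynamic_correct")
        assert main_steps[3].startswith("gaussian")
        assert main_steps[4].startswith("bandpass")

    def test_mice_truncated_to_common_length(self, coupled_session):
        _, _, _, processed = coupled_session
        lengths = {
            s.n_frames
            for stacks in processed.values()
            for s in stacks.values()
        }
        assert len(lengths) == 1

    def test_gfp_correction_reduces_variance(self, short_schedule):
        """In an activity-free (GFP) session, subtracting the
        reflectance channel can only remove shared artifact variance."""
        params = SessionParams(
            schedule=short_schedule, image_size=16, seed=21, gfp_mode=True
        )
        session, _ = simulate_session(params)
        processed = preprocess_session(session)
        for mouse in processed:
            corr = processed[mouse]["corrected"]
            green = processed[mouse]["green"]
            v_corr = corr.values[:, corr.mask].var()
            v_green = green.values[:, green.mask].var()
            assert v_corr <= v_green
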