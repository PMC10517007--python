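"""Noise level, SNR conventions, the neighbor peak rule, and the sweep."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trawlpam as tp
from trawlpam.snr import SensitivityCurve, SnrSeries
from .conftest import build_recovery_scene, detect_on_scene

FS = 4000  # 2-ms windows are 8 samples at this rate


def series_with_window_means(means, window_ms=2.0, nl=1.0):
    """An SnrSeries whose values are constant within each 2-ms window."""
    w = int(round(window_ms / 1000 * FS))
    values = np.repeat(np.asarray(means, dtype=float), w)
    return SnrSeries(values, FS, 0.0, tp.NoiseLevel(nl))


class TestNoiseLevel:
    def test_constant_block_rejected(self):
        block = tp.Recording(np.full(1000, 0.25), FS)
        with pytest.raises(ValueError, match="constant"):
            tp.estimate_noise_level(block)

    def test_alternating_samples_rms_identity(self):
        a = 0.3
        block = tp.Recording(np.tile([a, -a], 500), FS)
        assert tp.estimate_noise_level(block).nl == pytest.approx(a)

    def test_gaussian_block_matches_sample_rms(self):
        rng = np.random.default_rng(11)
        x = 0.1 * rng.standard_normal(200_000)
        block = tp.Recording(np.clip(x, -1, 1), FS)
        assert tp.estimate_noise_level(block).nl == pytest.approx(0.1, rel=0.01)

    def test_nl_db_is_20log10(self):
        assert tp.NoiseLevel(0.01).nl_db == pytest.approx(-40.0)


class TestSelectNoiseBlock:
    def test_auto_mode_avoids_event_blocks(self):
        """The quietest-tail block is one that holds no clicks."""
        fs = 96000
        noise = tp.make_noise(12.0, fs, rms=0.001, seed=3)
        trains = [tp.ClickTrainSpec(2.0 + k, [20.0] * 8, 0.3, 30000.0) for k in range(8)]
        scene, _ = tp.assemble_scene(noise, trains)
        blocks = tp.split_blocks(scene, 2.0)  # events occupy blocks 1..4 of 6
        assert tp.select_noise_block(blocks) in (0, 5)

    def test_explicit_index_passthrough(self):
        rec = tp.Recording(np.zeros(10_000) + 0.01, 1000)
        blocks = tp.split_blocks(rec, 1.0)
        assert tp.select_noise_block(blocks, 7) == 7

    def test_out_of_range_index_rejected(self):
        rec = tp.Recording(np.zeros(10_000) + 0.01, 1000)
        blocks = tp.split_blocks(rec, 1.0)
        with pytest.raises(ValueError, match="out of range"):
            tp.select_noise_block(blocks, 10)

    def test_single_block_warns(self):
        rec = tp.Recording(np.zeros(1000) + 0.01, 1000)
        blocks = tp.split_blocks(rec, 10.0)
        with pytest.warns(UserWarning, match="share"):
            assert tp.select_noise_block(blocks) == 0


class TestComputeSnr:
    def test_unity_ratio_is_zero_db_both_conventions(self):
        block = tp.Recording(np.tile([0.01, -0.01], 500), FS)
        noise = tp.NoiseLevel(0.01)
        for conv in ("eq1_literal", "power"):
            s = tp.compute_snr(block, noise, conv)
            assert np.allclose(s.values, 0.0)

    def test_ten_times_ratio(self):
        """|s| = 10*NL reads 10 dB as printed, 20 dB under the power convention."""
        block = tp.Recording(np.tile([0.1, -0.1], 500), FS)
        noise = tp.NoiseLevel(0.01)
        assert np.allclose(tp.compute_snr(block, noise, "eq1_literal").values, 10.0)
        assert np.allclose(tp.compute_snr(block, noise, "power").values, 20.0)

    def test_zero_samples_hit_floor(self):
        block = tp.Recording(np.array([0.5, -0.5, 0.5, -0.5, 0.0, 0.0]), FS)
        s = tp.compute_snr(block, tp.NoiseLevel(0.5))
        assert s.values[4] == s.floor_db == -100.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=1.0), st.integers(0, 2 ** 31 - 1))
    def test_scale_invariance(self, factor, seed):
        """Scaling the block and NL together leaves the SNR series unchanged."""
        rng = np.random.default_rng(seed)
        x = 0.5 * rng.uniform(-1, 1, 400)
        a = tp.compute_snr(tp.Recording(x, FS), tp.NoiseLevel(0.05))
        b = tp.compute_snr(tp.Recording(x * factor, FS), tp.NoiseLevel(0.05 * factor))
        assert np.allclose(a.values, b.values, atol=1e-9)


class TestDetectPeaks:
    def test_isolated_raised_window_is_a_peak(self):
        s = series_with_window_means([5, 12, 5])
        peaks = tp.detect_peaks(s, 10.0)
        assert len(peaks) == 1 and peaks[0].window_index == 1

    def test_adjacent_raised_windows_are_not_peaks(self):
        """Both raised windows fail the rule: each has a neighbor >= Th."""
        s = series_with_window_means([5, 12, 11, 5])
        assert tp.detect_peaks(s, 10.0) == []

    def test_boundary_windows_never_peak(self):
        s = series_with_window_means([12, 5, 5, 12])
        assert tp.detect_peaks(s, 10.0) == []

    def test_peak_time_is_window_center(self):
        s = series_with_window_means([5, 12, 5])
        (peak,) = tp.detect_peaks(s, 10.0)
        assert peak.time_s == pytest.approx(0.003)  # center of window 1 of 2 ms

    def test_peak_amplitude_recovered_from_snr(self):
        s = series_with_window_means([5, 12, 5], nl=0.01)
        (peak,) = tp.detect_peaks(s, 10.0)
        assert peak.peak_amplitude == pytest.approx(0.01 * 10 ** 1.2)

    def test_neighbor_rule_caps_peak_density(self):
        """No two adjacent windows can both be peaks, whatever the series."""
        rng = np.random.default_rng(5)
        s = series_with_window_means(rng.uniform(0, 20, 200))
        idx = [p.window_index for p in tp.detect_peaks(s, 10.0)]
        assert all(b - a >= 2 for a, b in zip(idx, idx[1:]))
        assert len(idx) <= 100

    def test_ground_truth_recovery_of_isolated_clicks(self):
        """20 window-centered clicks at 20 dB window SNR give exactly 20
        peaks, each within 2 ms of its ground-truth click."""
        fs = 96000
        noise = tp.make_noise(12.0, fs, rms=4e-5, lowfreq_fraction=0.0, seed=19)
        blocks = tp.split_blocks(noise, 5.0)
        nl = tp.estimate_noise_level(blocks.blocks[0]).nl
        amp = tp.click_amplitude_for_window_snr(
            20.0, nl, fs, tp.ClickTrainSpec(0.0, [1000.0], 1.0, 30000.0, 80.0))
        # ICI of 30 ms = 15 windows, started mid-window past the block edge:
        # every click is centered in its own interior window, the detector's
        # ideal geometry
        spec = tp.ClickTrainSpec(5.005, [30.0] * 19, amp, 30000.0, 80.0)
        scene, gt = tp.assemble_scene(noise, [spec])
        peaks, _, _ = detect_on_scene(scene, gt, 5.0)
        event_peaks = [p for p in peaks if p.time_s > 5.0]
        assert len(event_peaks) == 20
        times = np.array([p.time_s for p in event_peaks])
        assert all(np.min(np.abs(times - t)) <= 0.002 for t, _ in gt.clicks)


class TestThresholdSweep:
    def test_default_grid_has_25_points(self):
        s = series_with_window_means([0] * 40)
        curve = tp.threshold_sweep([s])
        assert curve.thresholds_db.size == 25
        assert curve.thresholds_db[0] == 4.0 and curve.thresholds_db[-1] == 16.0

    def test_counts_non_increasing_for_window_aligned_clicks(self):
        """Isolated one-window events only drop out as the threshold rises."""
        fs = 96000
        noise = tp.make_noise(8.0, fs, rms=4e-4, lowfreq_fraction=0.99, seed=13)
        filtered = tp.highpass(noise)
        nl = tp.estimate_noise_level(filtered).nl
        from trawlpam.synth import render_click

        rng = np.random.default_rng(13)
        bed = filtered.samples.copy()
        w = int(0.002 * fs)
        for k in range(40):  # one click per aligned window, varied strength
            amp = tp.click_amplitude_for_window_snr(
                rng.uniform(6.0, 15.0), nl, fs,
                tp.ClickTrainSpec(0.0, [1000.0], 1.0, 30000.0, 80.0))
            click = render_click(tp.ClickTrainSpec(0.0, [1000.0], amp, 30000.0, 80.0), fs)
            i = (4 * k + 1) * w + w // 3
            bed[i:i + click.size] += click
        block = tp.Recording(np.clip(bed, -1, 1), fs)
        series = tp.compute_snr(block, tp.NoiseLevel(nl))
        curve = tp.threshold_sweep([series])
        assert np.all(np.diff(curve.peak_counts) <= 0)

    def test_event_free_noise_has_no_peaks_at_plateau_threshold(self):
        """Gaussian noise alone yields (far) under 1 false alarm per minute at 10 dB."""
        fs = 96000
        noise = tp.make_noise(60.0, fs, rms=4e-4, lowfreq_fraction=0.99, seed=21)
        filtered = tp.highpass(noise)
        nl = tp.estimate_noise_level(filtered)
        series = tp.compute_snr(filtered, nl)
        assert len(tp.detect_peaks(series, 10.0)) < 1


class TestSelectThreshold:
    def test_hand_enumerated_plateau(self):
        """First point whose next four drops stay within 5% — here 5.5 dB."""
        curve = SensitivityCurve(
            np.arange(4.0, 8.0, 0.5), np.array([100, 50, 20, 10, 10, 10, 10, 10]))
        assert tp.select_threshold(curve) == 5.5
        assert curve.selected_th_db == 5.5

    def test_flat_curve_selects_first_point(self):
        curve = SensitivityCurve(np.arange(4.0, 8.0, 0.5), np.full(8, 42))
        assert tp.select_threshold(curve) == 4.0

    def test_decaying_curve_falls_back_to_midpoint(self):
        counts = (1000 / 2 ** np.arange(8)).astype(int)
        curve = SensitivityCurve(np.arange(4.0, 8.0, 0.5), counts)
        with pytest.warns(UserWarning, match="plateau"):
            assert tp.select_threshold(curve) == 6.0

    def test_too_few_points_rejected(self):
        curve = SensitivityCurve(np.arange(4.0, 5.0, 0.5), np.array([5, 5]))
        with pytest.raises(ValueError):
            tp.select_threshold(curve)
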