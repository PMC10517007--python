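"""The soundscape generator: determinism, spectra, placement, clipping."""

import numpy as np
import pytest
from scipy import signal

import trawlpam as tp
from trawlpam.synth import render_click


class TestMakeNoise:
    def test_rms_is_exact(self):
        rec = tp.make_noise(10.0, 48000, rms=0.01, lowfreq_fraction=0.5, seed=0)
        assert np.sqrt(np.mean(rec.samples ** 2)) == pytest.approx(0.01, rel=1e-3)

    def test_lowfreq_noise_removed_by_highpass(self):
        """Pure vessel-band noise nearly vanishes under the 10 kHz high-pass."""
        rec = tp.make_noise(10.0, 192000, rms=0.01, lowfreq_fraction=1.0, seed=1)
        filtered = tp.highpass(rec)
        residual = np.sqrt(np.mean(filtered.samples ** 2))
        assert residual < 0.05 * 0.01

    def test_same_seed_bit_identical(self):
        a = tp.make_noise(2.0, 48000, seed=42)
        b = tp.make_noise(2.0, 48000, seed=42)
        assert np.array_equal(a.samples, b.samples)

    def test_rms_bounds(self):
        with pytest.raises(ValueError):
            tp.make_noise(1.0, 48000, rms=0.6)
        with pytest.warns(UserWarning, match="headroom"):
            tp.make_noise(1.0, 48000, rms=0.3, seed=0)


class TestMakeClickTrain:
    def test_placement_arithmetic(self):
        """19 intervals of 5 ms place 20 clicks spanning 95 ms."""
        spec = tp.ClickTrainSpec(0.0, [5.0] * 19)
        _, times = tp.make_click_train(spec, 192000)
        assert len(times) == 20
        assert times[-1] - times[0] == pytest.approx(0.095)

    def test_decelerating_profile_gives_monotone_gaps(self):
        spec = tp.ClickTrainSpec(0.0, [60, 40, 20, 10, 5, 5, 5])
        _, times = tp.make_click_train(spec, 192000)
        gaps = np.diff(times)
        assert np.all(np.diff(gaps) <= 1e-12)

    def test_ici_shorter_than_click_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            tp.ClickTrainSpec(0.0, [0.05], click_duration_us=80.0)

    def test_carrier_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            tp.make_click_train(tp.ClickTrainSpec(0.0, [10.0], carrier_hz=60000.0), 96000)

    def test_click_times_are_local_maxima_of_clean_signal(self):
        """Each ground-truth time pins a waveform peak within half a click length."""
        spec = tp.ClickTrainSpec(0.01, [7.0] * 10, click_amplitude=0.5)
        rec, times = tp.make_click_train(spec, 192000)
        half = spec.click_duration_us * 1e-6 / 2
        x = np.abs(rec.samples)
        for t in times:
            i0 = int((t - half) * 192000)
            i1 = int((t + half) * 192000)
            local_peak_t = (i0 + np.argmax(x[max(i0, 0):i1])) / 192000
            assert abs(local_peak_t - t) <= half


class TestMakeWhistle:
    def test_linear_contour_frequency_at_midtime(self):
        """A 5->15 kHz sweep passes through ~10 kHz at its midpoint."""
        spec = tp.WhistleSpec(0.0, 1.0, [(0.0, 5000.0), (1.0, 15000.0)], amplitude=0.5)
        rec = tp.make_whistle(spec, 96000)
        mid = rec.samples[int(0.45 * 96000):int(0.55 * 96000)]
        f, pxx = signal.periodogram(mid, fs=96000)
        assert 9500 <= f[np.argmax(pxx)] <= 10500

    def test_constant_contour_is_pure_tone(self):
        spec = tp.WhistleSpec(0.0, 0.5, [(0.0, 10000.0), (1.0, 10000.0)], amplitude=0.5)
        rec = tp.make_whistle(spec, 96000)
        f, pxx = signal.periodogram(rec.samples, fs=96000)
        assert abs(f[np.argmax(pxx)] - 10000) < 50

    def test_amplitude_bound(self):
        spec = tp.WhistleSpec(0.0, 0.5, amplitude=0.3)
        rec = tp.make_whistle(spec, 96000)
        assert np.max(np.abs(rec.samples)) <= 0.3 + 1e-12

    def test_contour_above_nyquist_rejected(self):
        spec = tp.WhistleSpec(0.0, 0.5, [(0.0, 20000.0), (1.0, 50000.0)])
        with pytest.raises(ValueError, match="Nyquist"):
            tp.make_whistle(spec, 96000)


class TestAssembleScene:
    def test_noise_only_scene_logs_nothing(self):
        noise = tp.make_noise(2.0, 48000, seed=0)
        scene, log = tp.assemble_scene(noise)
        assert log.clicks == [] and log.trains == [] and log.whistles == []
        assert scene.duration_s == noise.duration_s

    def test_overlapping_whistles_are_concurrent(self):
        """Two whistles sharing 0.2 s both carry n_concurrent = 2 (the MW notion)."""
        noise = tp.make_noise(4.0, 48000, seed=0)
        ws = [
            tp.WhistleSpec(1.0, 0.5, [(0.0, 6000.0), (1.0, 9000.0)], 0.05),
            tp.WhistleSpec(1.3, 0.5, [(0.0, 9000.0), (1.0, 6000.0)], 0.05),
            tp.WhistleSpec(3.0, 0.5, [(0.0, 7000.0), (1.0, 8000.0)], 0.05),
        ]
        _, log = tp.assemble_scene(noise, whistles=ws)
        assert [w[2] for w in log.whistles] == [2, 2, 1]

    def test_every_click_inside_exactly_one_train_span(self):
        noise = tp.make_noise(5.0, 96000, seed=0)
        trains = [
            tp.ClickTrainSpec(1.0, [20.0] * 5, 0.4, carrier_hz=30000.0),
            tp.ClickTrainSpec(3.0, [50.0] * 5, 0.4, carrier_hz=30000.0),
        ]
        _, log = tp.assemble_scene(noise, trains)
        for t, _amp in log.clicks:
            holders = [s for s in log.trains if s[0] - 1e-9 <= t <= s[1] + 1e-9]
            assert len(holders) == 1

    def test_event_beyond_scene_rejected(self):
        noise = tp.make_noise(1.0, 48000, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            tp.assemble_scene(noise, whistles=[tp.WhistleSpec(0.8, 0.5)])

    def test_overdriven_mix_directs_to_inject_clipping(self):
        noise = tp.make_noise(1.0, 96000, rms=0.01, seed=0)
        trains = [
            tp.ClickTrainSpec(0.1, [10.0] * 3, 1.0, carrier_hz=24000.0),
            tp.ClickTrainSpec(0.1, [10.0] * 3, 1.0, carrier_hz=24000.0),
        ]
        with pytest.raises(ValueError, match="inject_clipping"):
            tp.assemble_scene(noise, trains)


class TestInjectClipping:
    def test_unity_gain_no_clipping(self):
        rec = tp.Recording(np.array([0.1, -0.5, 0.9]), 48000)
        out, spans = tp.inject_clipping(rec, 1.0)
        assert spans == []
        assert np.array_equal(out.samples, rec.samples)

    def test_constant_half_gain_four_clips_everything(self):
        rec = tp.Recording(np.full(1000, 0.5), 48000)
        out, spans = tp.inject_clipping(rec, 4.0)
        assert np.all(out.samples == 1.0)
        total = sum(round((e - s) * 48000) for s, e in spans)
        assert total == 1000

    def test_gain_below_one_rejected(self):
        rec = tp.Recording(np.array([0.1]), 48000)
        with pytest.raises(ValueError):
            tp.inject_clipping(rec, 0.5)

    def test_spans_agree_with_clipping_report(self):
        """Cross-module consistency: span samples == count at threshold 1.0."""
        rec = tp.make_noise(2.0, 48000, rms=0.1, seed=5)
        out, spans = tp.inject_clipping(rec, 6.0)
        span_samples = sum(round((e - s) * 48000) for s, e in spans)
        report = tp.clipped_fraction(out, 1.0)
        assert report.clipped_count == span_samples > 0


def test_mixing_raises_window_rms_monotonically():
    """Adding events can only add energy to the windows they occupy."""
    noise = tp.make_noise(3.0, 96000, seed=2)
    spec = tp.ClickTrainSpec(1.0, [30.0] * 6, 0.4, carrier_hz=30000.0)
    with_clicks, _ = tp.assemble_scene(noise, [spec])
    w = 96000 // 2
    for rec_a, rec_b in [(noise, with_clicks)]:
        ra = rec_a.samples[: 6 * w].reshape(6, w)
        rb = rec_b.samples[: 6 * w].reshape(6, w)
        assert np.all(np.sqrt((rb ** 2).mean(1)) >= np.sqrt((ra ** 2).mean(1)) - 1e-6)


def test_scene_from_config_round_trip(tmp_path):
    cfg = {
        "duration_s": 3.0, "sample_rate": 96000, "seed": 9,
        "noise": {"rms": 0.002, "lowfreq_fraction": 0.9},
        "trains": [{"start_s": 1.0, "ici_profile_ms": [20.0] * 4,
                    "click_amplitude": 0.4, "carrier_hz": 30000.0}],
        "whistles": [{"start_s": 2.0, "duration_s": 0.5,
                      "contour": [[0.0, 6000.0], [1.0, 9000.0]], "amplitude": 0.05}],
        "clipping_gain": 1.0,
    }
    a, log_a = tp.scene_from_config(cfg)
    b, log_b = tp.scene_from_config(cfg)
    assert np.array_equal(a.samples, b.samples)
    assert len(log_a.clicks) == 5 and len(log_a.whistles) == 1
    assert log_a.trains == log_b.trains


def test_ground_truth_log_save_load(tmp_path):
    _, log = tp.assemble_scene(
        tp.make_noise(2.0, 48000, seed=0),
        whistles=[tp.WhistleSpec(0.5, 0.5, amplitude=0.05)],
    )
    p = tmp_path / "gt.json"
    log.save(p)
    back = tp.GroundTruthLog.load(p)
    assert back.whistles == log.whistles and back.noise_rms == log.noise_rms
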