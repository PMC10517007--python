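"""Shared fixtures: small deterministic scenes built at test time."""

import numpy as np
import pytest

import trawlpam as tp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def build_recovery_scene(
    seed: int,
    mean_icis_ms,
    window_snr_db: float = 20.0,
    sample_rate: int = 96000,
    block_s: float = 10.0,
    n_clicks: int = 12,
    carrier_hz: float = 30000.0,
):
    """A scene whose clicks sit at a stated detection-window SNR.

    The noise bed is the white passband residual left after vessel-noise
    removal, so the detector is exercised in isolation (the high-pass stage
    has its own tests, and its ringing around strong transients is
    characterized in the docs). The first block is left event-free for noise
    estimation; click amplitudes are calibrated against the measured noise
    level of that block, so the ground-truth clicks really do carry
    ``window_snr_db`` at the detector's window statistic. Returns (scene,
    ground truth, block length).
    """
    rng = np.random.default_rng(seed)
    span = sum(m / 1000.0 * (n_clicks - 1) + 1.0 for m in mean_icis_ms)
    duration = block_s + span + 2.0
    noise = tp.make_noise(duration, sample_rate, rms=4e-5, lowfreq_fraction=0.0, seed=seed)
    blocks = tp.split_blocks(noise, block_s)
    nl = tp.estimate_noise_level(blocks.blocks[0]).nl
    trains = []
    t = block_s + 0.5
    for mean in mean_icis_ms:
        icis = rng.uniform(0.85 * mean, 1.15 * mean, size=n_clicks - 1).tolist()
        amp = tp.click_amplitude_for_window_snr(
            window_snr_db, nl, sample_rate,
            tp.ClickTrainSpec(0.0, [1000.0], 1.0, carrier_hz, 80.0),
        )
        trains.append(tp.ClickTrainSpec(t, icis, amp, carrier_hz, 80.0))
        t = trains[-1].end_s + 1.0
    scene, gt = tp.assemble_scene(noise, trains)
    return scene, gt, block_s


def detect_on_scene(scene, gt, block_s, th_db=10.0):
    """Run blocks -> NL -> SNR -> peaks on a recovery scene (passband input)."""
    blocks = tp.split_blocks(scene, block_s)
    noise = tp.estimate_noise_level(blocks.blocks[0], 0)
    series = [tp.compute_snr(b, noise, block_index=i) for i, b in enumerate(blocks.blocks)]
    peaks = [p for s in series for p in tp.detect_peaks(s, th_db)]
    return peaks, series, noise


@pytest.fixture(scope="session")
def recovery_scene():
    return build_recovery_scene(seed=7, mean_icis_ms=[5, 20, 35, 60, 90, 120])


@pytest.fixture(scope="session")
def demo():
    """The canonical 140-s study-conditions scene, generated once per session."""
    scene, gt = tp.demo_scene(seed=3)
    return scene, gt
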