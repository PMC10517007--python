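"""Synthetic underwater soundscapes with ground truth.

Generates WAV scenes carrying the statistical structure the click/whistle
analysis assumes: broadband vessel noise concentrated below 10 kHz,
echolocation click trains whose inter-click interval (ICI) follows the
search -> lock-on -> approach -> feeding-buzz progression, frequency-modulated
whistles in the 1-30 kHz band, concurrent (multiple-whistle) events, and
deliberate amplitude clipping. Every generated event is recorded in a
ground-truth log so downstream detectors can be scored without real data.

Clicks are modelled as exponentially decaying sinusoids (default carrier
60 kHz, within the 40-80 kHz dominant band reported for bottlenose dolphins;
default duration 80 us). Vessel noise is a mix of low-pass-shaped noise
(8th-order Butterworth at 8 kHz, so its energy sits safely below the 10 kHz
analysis cutoff) and white noise. None of this is a propagation model: see
docs/methods.md for what the generator does and does not emulate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import signal

from .formats import Recording

Contour = Union[Callable[[np.ndarray], np.ndarray], Sequence[Sequence[float]]]

#: shaping cutoff for the low-frequency (vessel) noise component, Hz
LOWFREQ_SHAPING_HZ = 8000.0


@dataclass
class ClickTrainSpec:
    """A click train: placement, ICI profile and click waveform parameters."""

    start_s: float
    ici_profile_ms: Sequence[float]
    click_amplitude: float = 0.6
    carrier_hz: float = 60000.0
    click_duration_us: float = 80.0

    def __post_init__(self):
        self.ici_profile_ms = list(self.ici_profile_ms)
        if any(i <= 0 for i in self.ici_profile_ms):
            raise ValueError("all ICIs must be positive")
        if not (0.0 < self.click_amplitude <= 1.0):
            raise ValueError("click_amplitude must lie in (0, 1]")
        if min(self.ici_profile_ms) * 1e-3 < self.click_duration_us * 1e-6:
            raise ValueError(
                "ICI shorter than the click duration: consecutive clicks would overlap"
            )

    @property
    def click_times_s(self) -> list[float]:
        """Exact placement time of every click (click k after the first k ICIs)."""
        t = [self.start_s]
        for ici in self.ici_profile_ms:
            t.append(t[-1] + ici / 1000.0)
        return t

    @property
    def end_s(self) -> float:
        return self.click_times_s[-1] + self.click_duration_us * 1e-6

    @property
    def true_mean_ici_ms(self) -> float:
        return float(np.mean(self.ici_profile_ms))


@dataclass
class WhistleSpec:
    """A frequency-modulated whistle: start, duration, contour and amplitude.

    ``contour`` maps relative time u in [0, 1] to instantaneous frequency in
    Hz, either as a callable or as a breakpoint list [(u, hz), ...] that is
    linearly interpolated.
    """

    start_s: float
    duration_s: float
    contour: Contour = ((0.0, 8000.0), (1.0, 12000.0))
    amplitude: float = 0.1

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (0.0 < self.amplitude <= 1.0):
            raise ValueError("amplitude must lie in (0, 1]")

    def frequencies(self, u: np.ndarray) -> np.ndarray:
        if callable(self.contour):
            return np.asarray(self.contour(u), dtype=float)
        pts = np.asarray(self.contour, dtype=float)
        return np.interp(u, pts[:, 0], pts[:, 1])

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class GroundTruthLog:
    """What the scene actually contains, for recovery scoring.

    clicks: (time_s, amplitude); trains: (start_s, end_s, true mean ICI ms);
    whistles: (start_s, end_s, n_concurrent); clipped_spans: (start_s, end_s);
    noise_rms: RMS of the noise bed alone.
    """

    clicks: list = field(default_factory=list)
    trains: list = field(default_factory=list)
    whistles: list = field(default_factory=list)
    clipped_spans: list = field(default_factory=list)
    noise_rms: float = 0.0

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({
            "clicks": self.clicks, "trains": self.trains, "whistles": self.whistles,
            "clipped_spans": self.clipped_spans, "noise_rms": self.noise_rms,
        }, indent=1))

    @classmethod
    def load(cls, path) -> "GroundTruthLog":
        d = json.loads(Path(path).read_text())
        return cls(
            clicks=[tuple(c) for c in d["clicks"]],
            trains=[tuple(t) for t in d["trains"]],
            whistles=[tuple(w) for w in d["whistles"]],
            clipped_spans=[tuple(s) for s in d["clipped_spans"]],
            noise_rms=d["noise_rms"],
        )


# --- Generators -----------------------------------------------------------


def make_noise(
    duration_s: float,
    sample_rate: int,
    rms: float = 0.003,
    lowfreq_fraction: float = 0.9,
    seed: Optional[int] = None,
) -> Recording:
    """Vessel-noise bed: low-pass-shaped plus white Gaussian noise.

    ``lowfreq_fraction`` is the share of total power placed in the shaped
    (below ~10 kHz) component. The result is rescaled to the requested RMS
    exactly; identical seeds give bit-identical output.
    """
    if not (0.0 < rms <= 0.5):
        raise ValueError(f"rms must lie in (0, 0.5], got {rms}")
    if rms > 0.2:
        warnings.warn(
            f"noise rms {rms} leaves little headroom: Gaussian peaks (~5 sigma) may exceed 1",
            stacklevel=2,
        )
    if not (0.0 <= lowfreq_fraction <= 1.0):
        raise ValueError("lowfreq_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    x = np.zeros(n)
    if lowfreq_fraction > 0.0:
        sos = signal.butter(8, LOWFREQ_SHAPING_HZ, "lowpass", fs=sample_rate, output="sos")
        low = signal.sosfiltfilt(sos, rng.standard_normal(n))
        x += np.sqrt(lowfreq_fraction) * low / np.sqrt(np.mean(low ** 2))
    if lowfreq_fraction < 1.0:
        white = rng.standard_normal(n)
        x += np.sqrt(1.0 - lowfreq_fraction) * white / np.sqrt(np.mean(white ** 2))
    x *= rms / np.sqrt(np.mean(x ** 2))
    if np.max(np.abs(x)) > 1.0:
        x = np.clip(x, -1.0, 1.0)  # only reachable near the warned rms bound
    return Recording(x, sample_rate)


def render_click(spec: ClickTrainSpec, sample_rate: int) -> np.ndarray:
    """One unit-placement click: decaying sinusoid, peak amplitude = spec's.

    The envelope time constant is a quarter of the click duration, so the
    waveform decays to e**-4 by the end of its nominal span.
    """
    n = max(int(round(spec.click_duration_us * 1e-6 * sample_rate)), 2)
    t = np.arange(n) / sample_rate
    tau = spec.click_duration_us * 1e-6 / 4.0
    return spec.click_amplitude * np.exp(-t / tau) * np.sin(2 * np.pi * spec.carrier_hz * t)


def make_click_train(spec: ClickTrainSpec, sample_rate: int) -> tuple[Recording, list[float]]:
    """Render a click train into a Recording spanning [0, end of train].

    Returns the waveform and the exact click placement times (seconds).
    """
    if spec.carrier_hz >= sample_rate / 2:
        raise ValueError(
            f"carrier {spec.carrier_hz} Hz is not below Nyquist ({sample_rate / 2} Hz)"
        )
    click = render_click(spec, sample_rate)
    times = spec.click_times_s
    n = int(round(times[-1] * sample_rate)) + click.size
    x = np.zeros(n)
    for t in times:
        i = int(round(t * sample_rate))
        x[i:i + click.size] += click
    peak = np.max(np.abs(x))
    if peak > 1.0:  # summed overlap cannot occur (ICI >= duration), but be safe
        x /= peak
    return Recording(x, sample_rate), times


def make_whistle(spec: WhistleSpec, sample_rate: int) -> Recording:
    """Render a phase-continuous FM whistle into a Recording spanning [0, end].

    Onset and offset are raised-cosine ramps of 10 ms (shortened for very
    brief whistles so the ramps never overlap).
    """
    n = int(round(spec.duration_s * sample_rate))
    u = np.arange(n) / max(n - 1, 1)
    freqs = spec.frequencies(u)
    if np.any(freqs >= sample_rate / 2):
        raise ValueError("whistle contour exceeds the Nyquist frequency")
    if np.any(freqs <= 0):
        raise ValueError("whistle contour must stay at positive frequency")
    phase = 2 * np.pi * np.cumsum(freqs) / sample_rate
    tone = np.sin(phase)
    ramp_n = min(int(round(0.010 * sample_rate)), n // 2)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        tone[:ramp_n] *= ramp
        tone[-ramp_n:] *= ramp[::-1]
    start_n = int(round(spec.start_s * sample_rate))
    x = np.zeros(start_n + n)
    x[start_n:] = spec.amplitude * tone
    return Recording(x, sample_rate)


def assemble_scene(
    noise: Recording,
    trains: Sequence[ClickTrainSpec] = (),
    whistles: Sequence[WhistleSpec] = (),
) -> tuple[Recording, GroundTruthLog]:
    """Additively mix events over the noise bed and log the ground truth.

    Whistles overlapping in time share n_concurrent > 1 (the deposit's "MW"
    notion). The mix must stay within [-1, +1]; deliberate overload goes
    through :func:`inject_clipping` afterwards.
    """
    fs = noise.sample_rate
    x = noise.samples.copy()
    log = GroundTruthLog(noise_rms=float(np.sqrt(np.mean(noise.samples ** 2))))
    for spec in trains:
        if spec.end_s > noise.duration_s:
            raise ValueError(f"train ending at {spec.end_s:.3f} s exceeds scene duration")
        rec, times = make_click_train(spec, fs)
        x[: rec.samples.size] += rec.samples
        log.clicks.extend((t, spec.click_amplitude) for t in times)
        log.trains.append((times[0], times[-1], spec.true_mean_ici_ms))
    for spec in whistles:
        if spec.end_s > noise.duration_s:
            raise ValueError(f"whistle ending at {spec.end_s:.3f} s exceeds scene duration")
        rec = make_whistle(spec, fs)
        x[: rec.samples.size] += rec.samples
    for spec in whistles:
        n_conc = sum(
            1 for other in whistles
            if other.start_s < spec.end_s and spec.start_s < other.end_s
        )
        log.whistles.append((spec.start_s, spec.end_s, n_conc))
    log.clicks.sort()
    log.trains.sort()
    log.whistles.sort()
    peak = float(np.max(np.abs(x)))
    if peak > 1.0:
        raise ValueError(
            f"mixed amplitude {peak:.3f} exceeds full scale; use inject_clipping "
            "for deliberate overload"
        )
    return Recording(x, fs, noise.bit_depth, noise.start_offset), log


def inject_clipping(recording: Recording, gain: float) -> tuple[Recording, list[tuple[float, float]]]:
    """Apply gain then hard-limit to [-1, +1]; return the clipped spans.

    Spans are maximal runs of limited samples, as half-open [start_s, end_s)
    intervals on the recording's clock.
    """
    if gain < 1.0:
        raise ValueError(f"gain must be >= 1, got {gain}")
    raw = recording.samples * gain
    mask = np.abs(raw) >= 1.0
    y = np.clip(raw, -1.0, 1.0)
    spans = []
    fs = recording.sample_rate
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        spans.append((recording.start_offset + i0 / fs, recording.start_offset + i1 / fs))
    return Recording(y, fs, recording.bit_depth, recording.start_offset), spans


# --- Detection-level calibration -------------------------------------------


def click_amplitude_for_window_snr(
    target_db: float,
    noise_rms: float,
    sample_rate: int,
    spec: Optional[ClickTrainSpec] = None,
    window_ms: float = 2.0,
    convention: str = "eq1_literal",
) -> float:
    """Peak amplitude at which one click yields a given window-mean SNR.

    The detector averages per-sample SNR over fixed windows in the linear
    domain; a click occupies a small fraction of a 2-ms window, so its
    window-level SNR is far below its per-sample peak SNR. This inverts that
    relationship so scenes can be built at a stated detection SNR.
    """
    ref = spec or ClickTrainSpec(0.0, [1000.0], click_amplitude=1.0)
    unit = render_click(
        ClickTrainSpec(0.0, [1000.0], 1.0, ref.carrier_hz, ref.click_duration_us), sample_rate
    )
    w = int(round(window_ms / 1000.0 * sample_rate))
    exponent = 1.0 if convention == "eq1_literal" else 2.0
    click_sum_unit = float(np.sum(np.abs(unit) ** exponent))
    # E|z|^1 = sqrt(2/pi), E|z|^2 = 1 for z ~ N(0, 1): the noise floor of the window mean
    noise_mean = np.sqrt(2 / np.pi) if exponent == 1.0 else 1.0
    target_lin = 10 ** (target_db / 10.0)
    need = (target_lin - noise_mean) * w
    if need <= 0:
        raise ValueError("target below the noise floor of the window statistic")
    amp = float((need * noise_rms ** exponent / click_sum_unit) ** (1 / exponent))
    if amp > 1.0:
        raise ValueError(
            f"required amplitude {amp:.3f} exceeds full scale; lower the noise or the target"
        )
    return amp


def filtered_noise_rms_estimate(
    rms: float,
    lowfreq_fraction: float,
    sample_rate: int,
    cutoff_hz: float = 10000.0,
) -> float:
    """Expected noise RMS after the analysis high-pass.

    The shaped component sits below the cutoff and is removed; the white
    component keeps the spectrum fraction above the cutoff.
    """
    nyq = sample_rate / 2.0
    return rms * np.sqrt((1.0 - lowfreq_fraction) * (nyq - cutoff_hz) / nyq)


# --- Scene configs ----------------------------------------------------------


def scene_from_config(config, seed: Optional[int] = None) -> tuple[Recording, GroundTruthLog]:
    """Build a scene from a structured config (dict or YAML file path).

    Keys: duration_s, sample_rate, seed, noise {rms, lowfreq_fraction},
    trains [{start_s, ici_profile_ms, click_amplitude, carrier_hz,
    click_duration_us}], whistles [{start_s, duration_s, contour, amplitude}],
    clipping_gain (optional). A ``seed`` argument overrides the config's.
    """
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    fs = int(cfg.get("sample_rate", 192000))
    duration = float(cfg["duration_s"])
    use_seed = seed if seed is not None else cfg.get("seed")
    noise_cfg = cfg.get("noise", {})
    noise = make_noise(
        duration, fs,
        rms=float(noise_cfg.get("rms", 0.003)),
        lowfreq_fraction=float(noise_cfg.get("lowfreq_fraction", 0.9)),
        seed=use_seed,
    )
    trains = [ClickTrainSpec(**t) for t in cfg.get("trains", [])]
    whistles = [
        WhistleSpec(
            start_s=w["start_s"], duration_s=w["duration_s"],
            contour=[tuple(p) for p in w.get("contour", [(0.0, 8000.0), (1.0, 12000.0)])],
            amplitude=float(w.get("amplitude", 0.1)),
        )
        for w in cfg.get("whistles", [])
    ]
    scene, log = assemble_scene(noise, trains, whistles)
    gain = float(cfg.get("clipping_gain", 1.0))
    if gain > 1.0:
        scene, spans = inject_clipping(scene, gain)
        log.clipped_spans = spans
    return scene, log


def demo_scene(
    seed: int = 0,
    duration_s: float = 140.0,
    sample_rate: int = 192000,
) -> tuple[Recording, GroundTruthLog]:
    """A study-conditions scene: the canonical fixture for the full pipeline.

    140 s (two full 60-s blocks plus a 20-s remainder, echoing the study's
    segmentation) of vessel noise with a behavioral mixture dominated by
    feeding buzzes, a spread of lock-on/approach trains, a few slow search
    trains, whistles of 0.4-0.8 s in the 1-30 kHz band including one
    concurrent pair, and mild overload of the strongest clicks. The first
    60-s block is kept free of dolphin vocalizations so it can serve as the
    noise block. Sparse impulsive gear transients (net and chain clanks)
    run through the whole scene at detection-level SNRs of 3-10 dB: they are
    what makes the threshold sensitivity curve decay and then plateau, as a
    curve over pure Gaussian noise would be flat.
    """
    rng = np.random.default_rng(seed)
    noise = make_noise(duration_s, sample_rate, rms=0.0015, lowfreq_fraction=0.995, seed=seed)
    nl_est = filtered_noise_rms_estimate(0.0015, 0.995, sample_rate)
    bed = noise.samples.copy()
    for _ in range(int(0.4 * duration_s)):  # sparse clanks, a few per 10 s
        snr_db = rng.uniform(3.5, 9.5)
        spec = ClickTrainSpec(
            0.0, [1000.0],
            click_amplitude=click_amplitude_for_window_snr(
                snr_db, nl_est, sample_rate,
                ClickTrainSpec(0.0, [1000.0], 1.0, rng.uniform(15000, 80000), 60.0),
            ),
            carrier_hz=rng.uniform(15000, 80000), click_duration_us=60.0,
        )
        clank = render_click(spec, sample_rate)
        i = int(rng.uniform(0.5, duration_s - 0.5) * sample_rate)
        bed[i:i + clank.size] += clank
    noise = Recording(np.clip(bed, -1, 1), sample_rate)

    def train(start, mean_ici, n_clicks, amp):
        icis = rng.uniform(0.8 * mean_ici, 1.2 * mean_ici, size=n_clicks - 1)
        return ClickTrainSpec(start, icis.tolist(), click_amplitude=amp)

    trains = []
    t = 62.0
    # feeding buzzes dominate, as in the depredation context
    for _ in range(6):
        trains.append(train(t, rng.uniform(3.5, 8.0), int(rng.integers(15, 30)), 0.62))
        t += rng.uniform(1.2, 2.5)
    for _ in range(4):  # approach / lock-on
        trains.append(train(t, rng.uniform(15.0, 45.0), int(rng.integers(10, 18)), 0.55))
        t += rng.uniform(2.0, 4.0)
    for _ in range(2):  # search
        trains.append(train(t, rng.uniform(55.0, 90.0), int(rng.integers(8, 12)), 0.5))
        t += rng.uniform(3.0, 5.0)
    trains.append(train(t, 115.0, 6, 0.5))  # the rare slow train

    whistles = [
        WhistleSpec(64.0, 0.6, [(0.0, 6000.0), (0.5, 14000.0), (1.0, 9000.0)], 0.05),
        WhistleSpec(70.0, 0.45, [(0.0, 4000.0), (1.0, 11000.0)], 0.06),
        WhistleSpec(86.0, 0.8, [(0.0, 9000.0), (0.4, 18000.0), (1.0, 12000.0)], 0.07),
        # a concurrent (MW) pair
        WhistleSpec(101.0, 0.7, [(0.0, 5000.0), (1.0, 16000.0)], 0.05),
        WhistleSpec(101.3, 0.6, [(0.0, 12000.0), (1.0, 7000.0)], 0.05),
        WhistleSpec(126.0, 0.5, [(0.0, 20000.0), (1.0, 26000.0)], 0.06),
    ]
    scene, log = assemble_scene(noise, trains, whistles)
    scene, spans = inject_clipping(scene, 3.0)
    log.clipped_spans = spans
    return scene, log
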