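"""Whistle catalog: per-segment SNR, per-class statistics, and spectrograms.

Whistle detection itself is a human act (visual inspection of spectrograms);
this module manages the resulting catalog: start/end times, single vs
multiple-whistle tags (W/MW), quality classes 1-3 (1 = weak, 3 = prominent),
the duration and mean SNR of each segment, per-class means with standard
errors, pairwise class comparisons, and the study-style spectrogram rendering
(Hann window of 1024 points, 4-second view).

A segment's mean SNR averages the amplitude-to-noise ratio over the segment
in the linear domain and converts to dB, so a pure tone of peak amplitude
A reads k*log10((A/NL) * 2/pi) — the 2/pi factor is the mean of |sin|.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .formats import LabelEntry, Recording
from .snr import NoiseLevel, _CONVENTION_K


@dataclass
class WhistleSegment:
    """One cataloged whistle (or concurrent whistle group)."""

    id: int
    start_s: float
    end_s: float
    tag: str = "W"
    quality_class: Optional[int] = None
    mean_snr_db: Optional[float] = None

    def __post_init__(self):
        if self.id < 1:
            raise ValueError("whistle ids count from 1")
        if not self.end_s > self.start_s:
            raise ValueError("end_s must exceed start_s")
        if self.tag not in ("W", "MW"):
            raise ValueError(f"tag must be 'W' or 'MW', got {self.tag!r}")
        if self.quality_class is not None and self.quality_class not in (1, 2, 3):
            raise ValueError("quality_class must be 1, 2 or 3")

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


@dataclass
class ClassStats:
    """Per-quality-class summary: n, mean +/- SE of duration and SNR."""

    quality_class: int
    n: int
    mean_duration_ms: Optional[float] = None
    se_duration_ms: Optional[float] = None
    mean_snr_db: Optional[float] = None
    se_snr_db: Optional[float] = None


@dataclass
class ComparisonResult:
    class_a: int
    class_b: int
    p_value: float
    significant: bool


def catalog_from_labels(entries: Sequence[LabelEntry]) -> list[WhistleSegment]:
    """Whistle segments from label-track entries, ids sequential in order."""
    return [
        WhistleSegment(i, e.start_s, e.end_s, e.tag or "W", e.quality_class)
        for i, e in enumerate(entries, start=1)
    ]


def catalog_to_labels(catalog: Sequence[WhistleSegment]) -> list[LabelEntry]:
    return [LabelEntry(s.start_s, s.end_s, s.tag, s.quality_class) for s in catalog]


def whistle_mean_snr(
    recording: Recording,
    seg: WhistleSegment,
    noise: NoiseLevel,
    convention: str = "eq1_literal",
) -> float:
    """Mean SNR of a segment: dB of the mean linear amplitude ratio.

    Samples are mean-removed over the segment; the ratio |s|/NL is averaged in
    the linear domain and mapped to dB with the active convention, so doubling
    both signal and NL leaves the value unchanged.
    """
    k = _CONVENTION_K[convention]
    cut = recording.slice_seconds(seg.start_s, seg.end_s)
    x = cut.samples - np.mean(cut.samples)
    mean_ratio = float(np.mean(np.abs(x))) / noise.nl
    if mean_ratio == 0.0:
        raise ValueError("segment is constant: SNR undefined")
    return float(k * np.log10(mean_ratio))


def attach_snr(
    recording: Recording,
    catalog: Sequence[WhistleSegment],
    noise: NoiseLevel,
    convention: str = "eq1_literal",
) -> list[WhistleSegment]:
    """Catalog copy with mean_snr_db computed from the audio."""
    return [
        replace(seg, mean_snr_db=whistle_mean_snr(recording, seg, noise, convention))
        for seg in catalog
    ]


def class_stats(catalog: Sequence[WhistleSegment]) -> dict[int, ClassStats]:
    """Per-class n, mean and standard error (sample SD / sqrt(n)).

    SE is undefined (None) for classes with fewer than two members; SNR
    columns are None when segments carry no mean_snr_db.
    """
    out: dict[int, ClassStats] = {}
    for cls in (1, 2, 3):
        segs = [s for s in catalog if s.quality_class == cls]
        n = len(segs)
        if n == 0:
            out[cls] = ClassStats(cls, 0)
            continue
        durations = np.array([s.duration_ms for s in segs])
        snrs = np.array([s.mean_snr_db for s in segs if s.mean_snr_db is not None])

        def mean_se(vals):
            if vals.size == 0:
                return None, None
            m = float(np.mean(vals))
            se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 else None
            return m, se

        md, sd = mean_se(durations)
        ms, ss = mean_se(snrs)
        out[cls] = ClassStats(cls, n, md, sd, ms, ss)
    return out


def stats_table(stats_by_class: dict[int, ClassStats]):
    """Quality-class summary as a DataFrame shaped like the deposit's table."""
    import pandas as pd

    return pd.DataFrame([
        {
            "class": s.quality_class, "n": s.n,
            "mean_duration_ms": s.mean_duration_ms, "se_duration_ms": s.se_duration_ms,
            "mean_snr_db": s.mean_snr_db, "se_snr_db": s.se_snr_db,
        }
        for s in stats_by_class.values()
    ])


def compare_classes(
    values_by_class: dict[int, Sequence[float]],
    test: str = "welch_t",
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Two-sided pairwise tests between quality classes.

    Welch's t by default (no equal-variance assumption); Mann-Whitney U as a
    distribution-free alternative. Zero-variance inputs are rejected by name.
    """
    for cls, vals in values_by_class.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise ValueError(f"class {cls} needs at least 2 values")
        if np.std(vals) == 0.0:
            raise ValueError(f"class {cls} has zero variance: test degenerate")
    results = []
    for a, b in itertools.combinations(sorted(values_by_class), 2):
        va, vb = values_by_class[a], values_by_class[b]
        if test == "welch_t":
            p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        elif test == "mann_whitney":
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        else:
            raise ValueError("test must be 'welch_t' or 'mann_whitney'")
        results.append(ComparisonResult(a, b, p, p < alpha))
    return results


@dataclass
class Spectrogram:
    """Magnitude spectrogram of a whistle's 4-second view."""

    freqs_hz: np.ndarray
    times_s: np.ndarray
    magnitude: np.ndarray
    segment_id: int

    def peak_frequency_at(self, t_s: float) -> float:
        """Frequency of the strongest bin in the column nearest t_s."""
        col = int(np.argmin(np.abs(self.times_s - t_s)))
        return float(self.freqs_hz[np.argmax(self.magnitude[:, col])])

    def save_png(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        db = 20 * np.log10(self.magnitude + 1e-12)
        ax.pcolormesh(self.times_s, self.freqs_hz / 1000.0, db, shading="auto", cmap="magma")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (kHz)")
        ax.set_title(f"whistle {self.segment_id:03d}")
        fig.tight_layout()
        fig.savefig(path, dpi=80)
        plt.close(fig)


def render_spectrogram(
    recording: Recording,
    seg: WhistleSegment,
    window_points: int = 1024,
    view_s: float = 4.0,
    overlap: float = 0.5,
) -> Spectrogram:
    """Hann-window magnitude spectrogram of the segment's 4-second view.

    The view is centered on the segment and truncated at the recording's
    edges. Frequency resolution is sample_rate / window_points (187.5 Hz at
    192 kHz).
    """
    center = (seg.start_s + seg.end_s) / 2.0
    lo = max(center - view_s / 2.0, recording.start_offset)
    hi = min(center + view_s / 2.0, recording.end_offset)
    cut = recording.slice_seconds(lo, hi)
    nperseg = min(window_points, cut.samples.size)
    f, t, mag = sps.spectrogram(
        cut.samples, fs=recording.sample_rate,
        window=sps.windows.hann(nperseg), nperseg=nperseg,
        noverlap=int(nperseg * overlap), mode="magnitude",
    )
    return Spectrogram(f, t + lo, mag, seg.id)


def export_spectrograms(recording: Recording, catalog: Sequence[WhistleSegment], directory) -> list[Path]:
    """One PNG per catalog entry, named <id>_whistle_spectro.png."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for seg in catalog:
        spec = render_spectrogram(recording, seg)
        out = directory / f"{seg.id:03d}_whistle_spectro.png"
        spec.save_png(out)
        paths.append(out)
    return paths
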