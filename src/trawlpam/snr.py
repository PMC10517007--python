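"""Noise-level estimation, per-sample SNR, and SNR-threshold peak detection.

The noise level NL is the RMS of a vocalization-free block (mean-removed).
Per-sample SNR follows the printed formula SNR(t) = 10*log10(SIGNAL(t)/NL)
with SIGNAL taken as the absolute mean-removed sample ("eq1_literal"); the
physically conventional 20*log10 mapping is available as convention="power".

Peaks are found on consecutive non-overlapping 2-ms windows: a window is a
peak iff its mean SNR exceeds the threshold Th while both neighboring window
means sit below Th. Window means are taken in the linear domain by default
(10*log10 of the mean of 10**(v/10)); averaging the dB values themselves
(mean_mode="db") is supported but lets the many noise samples of a window
swamp a short transient — see docs/methods.md.

The threshold itself comes from a sensitivity sweep (4-16 dB in 0.5-dB
steps): the selected Th is the first grid point after which the peak count
plateaus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats import Recording
from .preprocess import BlockSet


@dataclass
class NoiseLevel:
    """Linear RMS amplitude of the reference noise block."""

    nl: float
    source_block: Optional[int] = None

    def __post_init__(self):
        if not self.nl > 0:
            raise ValueError("noise level must be positive (all-zero block?)")

    @property
    def nl_db(self) -> float:
        """dBrms re full scale."""
        return 20.0 * np.log10(self.nl)


_CONVENTION_K = {"eq1_literal": 10.0, "power": 20.0}


@dataclass
class SnrSeries:
    """Per-sample SNR (dB) for one block, with enough context to invert it."""

    values: np.ndarray
    sample_rate: int
    start_offset: float
    noise: NoiseLevel
    convention: str = "eq1_literal"
    block_index: int = 0
    floor_db: float = -100.0

    @property
    def k(self) -> float:
        return _CONVENTION_K[self.convention]


@dataclass
class Peak:
    """A detected transient: one 2-ms window whose mean SNR stands alone above Th."""

    time_s: float
    window_index: int
    mean_snr_db: float
    peak_amplitude: float


@dataclass
class SensitivityCurve:
    """Peak counts across the threshold grid, plus the selected plateau point."""

    thresholds_db: np.ndarray
    peak_counts: np.ndarray
    selected_th_db: Optional[float] = None


def estimate_noise_level(block: Recording, source_block: Optional[int] = None) -> NoiseLevel:
    """NL = RMS of the mean-removed samples of a vocalization-free block."""
    x = block.samples - np.mean(block.samples)
    rms = float(np.sqrt(np.mean(x ** 2)))
    if rms == 0.0:
        raise ValueError("block is constant: noise level would be zero")
    return NoiseLevel(rms, source_block)


def select_noise_block(blocks: BlockSet, index: Optional[int] = None) -> int:
    """Pick the reference noise block.

    With an explicit index the choice is the caller's (mirroring the study's
    visual inspection). In automatic mode, the block minimizing the 99th
    percentile of |sample| is used as a proxy for "no vocalizations": blocks
    holding clicks or whistles have heavier amplitude tails.
    """
    if index is not None:
        if not (0 <= index < blocks.n_blocks):
            raise ValueError(f"noise block index {index} out of range 0..{blocks.n_blocks - 1}")
        return index
    if blocks.n_blocks == 1:
        warnings.warn("single-block recording: noise and signal share a block", stacklevel=2)
        return 0
    scores = [np.percentile(np.abs(b.samples), 99) for b in blocks.blocks]
    return int(np.argmin(scores))


def compute_snr(
    block: Recording,
    noise: NoiseLevel,
    convention: str = "eq1_literal",
    floor_db: float = -100.0,
    block_index: int = 0,
) -> SnrSeries:
    """Per-sample SNR in dB for one block.

    Samples are mean-removed over the block; zero-amplitude samples map to a
    finite floor so window means stay defined. Scaling the block and NL by a
    common factor leaves the series unchanged.
    """
    if convention not in _CONVENTION_K:
        raise ValueError(f"convention must be one of {sorted(_CONVENTION_K)}")
    k = _CONVENTION_K[convention]
    x = np.abs(block.samples - np.mean(block.samples)) / noise.nl
    with np.errstate(divide="ignore"):
        v = k * np.log10(x)
    v = np.where(np.isfinite(v), v, floor_db)
    v = np.maximum(v, floor_db)
    return SnrSeries(v, block.sample_rate, block.start_offset, noise,
                     convention, block_index, floor_db)


def window_means(snr: SnrSeries, window_ms: float = 2.0, mean_mode: str = "linear") -> np.ndarray:
    """Mean SNR over consecutive non-overlapping windows (trailing remainder dropped).

    mean_mode="linear": 10*log10 of the mean of 10**(v/10) — energy-like
    averaging that lets a short transient raise its window. mean_mode="db":
    plain average of the dB values.
    """
    w = int(round(window_ms / 1000.0 * snr.sample_rate))
    if w < 1:
        raise ValueError("window shorter than one sample")
    n_win = snr.values.size // w
    v = snr.values[: n_win * w].reshape(n_win, w)
    if mean_mode == "linear":
        return 10.0 * np.log10(np.mean(10.0 ** (v / 10.0), axis=1))
    if mean_mode == "db":
        return v.mean(axis=1)
    raise ValueError("mean_mode must be 'linear' or 'db'")


def _peak_mask(means: np.ndarray, th_db: float) -> np.ndarray:
    """Neighbor rule on window means; boundary windows are never peaks."""
    mask = np.zeros(means.size, dtype=bool)
    if means.size >= 3:
        mask[1:-1] = (means[1:-1] > th_db) & (means[:-2] < th_db) & (means[2:] < th_db)
    return mask


def detect_peaks(
    snr: SnrSeries,
    th_db: float,
    window_ms: float = 2.0,
    mean_mode: str = "linear",
) -> list[Peak]:
    """Detect isolated above-threshold windows in one block.

    Window w is a peak iff mean(w) > Th and both neighboring means are below
    Th; the first and last windows have a missing neighbor and are never
    peaks. The peak time is the window center on the original clock, and
    ``peak_amplitude`` is the largest |sample| in the window, recovered from
    the SNR series and the noise level.
    """
    w = int(round(window_ms / 1000.0 * snr.sample_rate))
    means = window_means(snr, window_ms, mean_mode)
    mask = _peak_mask(means, th_db)
    n_win = means.size
    vmax = snr.values[: n_win * w].reshape(n_win, w).max(axis=1)
    peaks = []
    for idx in np.flatnonzero(mask):
        amp = snr.noise.nl * 10.0 ** (vmax[idx] / snr.k)
        t = snr.start_offset + (idx + 0.5) * w / snr.sample_rate
        peaks.append(Peak(t, int(idx), float(means[idx]), float(amp)))
    return peaks


def threshold_sweep(
    snr_blocks: Sequence[SnrSeries],
    th_min_db: float = 4.0,
    th_max_db: float = 16.0,
    step_db: float = 0.5,
    window_ms: float = 2.0,
    mean_mode: str = "linear",
) -> SensitivityCurve:
    """Total peak count over all blocks at every threshold of the grid.

    Endpoints are inclusive; the study grid 4..16 dB by 0.5 dB has 25 points.
    """
    if not (th_min_db < th_max_db and step_db > 0):
        raise ValueError("need th_min < th_max and step > 0")
    n = int(round((th_max_db - th_min_db) / step_db)) + 1
    thresholds = np.linspace(th_min_db, th_max_db, n)
    all_means = [window_means(s, window_ms, mean_mode) for s in snr_blocks]
    counts = np.array([
        sum(int(_peak_mask(m, th).sum()) for m in all_means) for th in thresholds
    ])
    return SensitivityCurve(thresholds, counts)


def select_threshold(
    curve: SensitivityCurve,
    rel_tol: float = 0.05,
    lookahead: int = 4,
) -> float:
    """First threshold after which the peak count plateaus.

    Returns the smallest grid point t such that, for each of the next
    ``lookahead`` points, the relative drop in peak count from t is at most
    ``rel_tol``. The count at t must be positive: the curve's all-zero tail
    is flat too, but a threshold that detects nothing is not a stabilization
    of the detection. Falls back to the grid midpoint with a warning when no
    point qualifies (a strictly decaying curve has no plateau).
    """
    counts = np.asarray(curve.peak_counts, dtype=float)
    if counts.size < lookahead + 1:
        raise ValueError(f"curve needs at least {lookahead + 1} points")
    for i in range(counts.size - lookahead):
        c = counts[i]
        drops = c - counts[i + 1: i + 1 + lookahead]
        if c > 0 and np.all(drops <= rel_tol * c):
            curve.selected_th_db = float(curve.thresholds_db[i])
            return curve.selected_th_db
    warnings.warn(
        "no plateau found in the sensitivity curve; falling back to the grid midpoint",
        stacklevel=2,
    )
    curve.selected_th_db = float(curve.thresholds_db[counts.size // 2])
    return curve.selected_th_db
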