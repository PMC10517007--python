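"""Click-train segmentation, ICI statistics and behavioral phase labels.

Detected peaks are first cleaned of reverberation copies (a trailing peak much
weaker than, and close behind, a retained one), then grouped into trains with
an adaptive inter-click-interval rule: the next peak joins the current train
iff its gap does not exceed min(250 ms, 3 x the running median ICI of the
train). 250 ms is the dataset's stated minimum separation between trains; the
median factor adapts the rule from feeding buzzes (ICI of a few ms) up to
slow search trains. Trains need at least 3 peaks (2 ICIs) for a meaningful
mean ICI.

Mean ICI indexes the behavioral phase of echolocation: search (slow trains),
lock-on, approach, and the terminal feeding buzz below 10 ms. The literature
ranges overlap between 30 and 40 ms; the mapping here is disjointized at
30 ms so every train gets exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats import BlockResult, LabelEntry
from .snr import Peak

PHASES = ("feeding_buzz", "approach", "lock_on", "search", "unclassified")


def heal_gaps(icis_ms: Sequence[float], tolerance: float = 0.15,
              max_multiple: int = 3) -> list[float]:
    """Split gaps left by detector-missed clicks back into unit intervals.

    A detector occasionally drops a click (e.g. one straddling a window
    boundary); the train then shows a gap close to an integer multiple of its
    typical interval, which would inflate the mean ICI. A gap within
    ``tolerance`` (relative) of k x the train's median interval, 2 <= k <=
    ``max_multiple``, is counted as k intervals of gap/k. Regular trains pass
    through unchanged.
    """
    if not icis_ms:
        return []
    med = float(np.median(icis_ms))
    out: list[float] = []
    for g in icis_ms:
        k = int(round(g / med))
        if 2 <= k <= max_multiple and abs(g / (k * med) - 1.0) <= tolerance:
            out.extend([g / k] * k)
        else:
            out.append(g)
    return out


@dataclass
class ClickTrain:
    """An ordered click sequence from (presumably) one animal.

    ``icis_ms`` are the raw inter-peak gaps (one per consecutive detected
    pair); the summary statistics are computed on the gap-healed intervals so
    a single missed click does not bias the train's mean ICI.
    """

    peak_times_s: list[float]
    icis_ms: list[float]
    phase: str = "unclassified"

    def __post_init__(self):
        if len(self.peak_times_s) < 3:
            raise ValueError("a train needs at least 3 peaks")
        if len(self.icis_ms) != len(self.peak_times_s) - 1:
            raise ValueError("need exactly one ICI per consecutive peak pair")

    @property
    def start_s(self) -> float:
        return self.peak_times_s[0]

    @property
    def end_s(self) -> float:
        return self.peak_times_s[-1]

    @property
    def healed_icis_ms(self) -> list[float]:
        return heal_gaps(self.icis_ms)

    @property
    def mean_ici_ms(self) -> float:
        return float(np.mean(self.healed_icis_ms))

    @property
    def min_ici_ms(self) -> float:
        return float(np.min(self.healed_icis_ms))

    @property
    def max_ici_ms(self) -> float:
        return float(np.max(self.healed_icis_ms))


@dataclass
class IciHistogram:
    """Trains binned by mean ICI into 5-ms bins [0,5), [5,10), ..."""

    bin_width_ms: float
    bin_edges_ms: np.ndarray
    counts: np.ndarray

    @property
    def bin_labels(self) -> list[str]:
        """Bins labeled by their upper edge, as in the deposit's clicks.txt."""
        return [f"{edge:g}" for edge in self.bin_edges_ms[1:]]


def filter_reverbs(
    peaks: Sequence[Peak],
    echo_window_ms: float = 5.0,
    amplitude_ratio: float = 0.5,
) -> list[Peak]:
    """Drop reverberation copies from a time-sorted peak stream.

    Scanning left to right, a peak is removed iff it lies within
    ``echo_window_ms`` after the most recently retained peak AND its amplitude
    is below ``amplitude_ratio`` times that peak's. Comparable-amplitude
    neighbors (e.g. genuine buzz clicks a few ms apart) are kept. The filter
    never removes the first peak and is idempotent.
    """
    times = [p.time_s for p in peaks]
    if any(times[i] < times[i - 1] for i in range(1, len(times))):
        raise ValueError("peaks must be sorted by time")
    kept: list[Peak] = []
    for p in peaks:
        if kept:
            ref = kept[-1]
            if ((p.time_s - ref.time_s) * 1000.0 <= echo_window_ms
                    and p.peak_amplitude < amplitude_ratio * ref.peak_amplitude):
                continue
        kept.append(p)
    return kept


def segment_trains(
    peaks: Sequence[Peak],
    ici_factor: float = 3.0,
    max_gap_ms: float = 250.0,
    min_peaks: int = 3,
) -> list[ClickTrain]:
    """Group a reverb-filtered, time-sorted peak stream into click trains.

    The adaptive rule: a peak joins the current train iff its gap to the last
    member is <= min(max_gap_ms, ici_factor x running median of the train's
    ICIs); a train that has no ICI history yet accepts any gap up to
    max_gap_ms. Fragments with fewer than ``min_peaks`` peaks are discarded.
    """
    times = [p.time_s for p in peaks]
    if any(times[i] < times[i - 1] for i in range(1, len(times))):
        raise ValueError("peaks must be sorted by time")
    trains: list[ClickTrain] = []
    cur: list[float] = []
    icis: list[float] = []

    def flush():
        if len(cur) >= min_peaks:
            trains.append(_build_train(cur, icis))

    for t in times:
        if not cur:
            cur.append(t)
            continue
        gap_ms = (t - cur[-1]) * 1000.0
        limit = max_gap_ms if not icis else min(max_gap_ms, ici_factor * float(np.median(icis)))
        if gap_ms <= limit:
            cur.append(t)
            icis.append(gap_ms)
        else:
            flush()
            cur, icis = [t], []
    flush()
    return trains


def _build_train(times: list[float], icis: list[float]) -> ClickTrain:
    train = ClickTrain(list(times), list(icis))
    train.phase = label_phase(train.mean_ici_ms)
    return train


def label_phase(mean_ici_ms: float) -> str:
    """Behavioral phase from a train's mean ICI.

    [0, 10) ms feeding buzz; [10, 30) approach; [30, 50) lock-on;
    [50, 500] search; above 500 ms unclassified (beyond the echolocation
    progression).
    """
    if mean_ici_ms <= 0:
        raise ValueError(f"mean ICI must be positive, got {mean_ici_ms}")
    if mean_ici_ms < 10:
        return "feeding_buzz"
    if mean_ici_ms < 30:
        return "approach"
    if mean_ici_ms < 50:
        return "lock_on"
    if mean_ici_ms <= 500:
        return "search"
    return "unclassified"


def ici_bin_label(mean_ici_ms: float, bin_width_ms: float = 5.0) -> str:
    """Label of the 5-ms mean-ICI bin containing a value (by upper edge)."""
    upper = (int(mean_ici_ms // bin_width_ms) + 1) * bin_width_ms
    return f"{upper:g}"


def ici_histogram(trains: Sequence[ClickTrain], bin_width_ms: float = 5.0) -> IciHistogram:
    """Histogram of trains by mean ICI in fixed-width bins from zero."""
    means = np.array([t.mean_ici_ms for t in trains], dtype=float)
    top = bin_width_ms if means.size == 0 else (np.floor(means.max() / bin_width_ms) + 1) * bin_width_ms
    edges = np.arange(0.0, top + bin_width_ms / 2, bin_width_ms)
    counts, _ = np.histogram(means, bins=edges)
    return IciHistogram(bin_width_ms, edges, counts)


def trains_to_label_entries(trains: Sequence[ClickTrain], bin_width_ms: float = 5.0) -> list[LabelEntry]:
    """clicks.txt entries: train span labeled with its mean-ICI bin."""
    return [
        LabelEntry(t.start_s, t.end_s, ici_bin_label(t.mean_ici_ms, bin_width_ms))
        for t in sorted(trains, key=lambda t: t.start_s)
    ]


def per_block_results(
    trains: Sequence[ClickTrain],
    peaks: Sequence[Peak],
    whistles: Sequence = (),
    n_blocks: int = 1,
    block_length_s: float = 60.0,
) -> list[BlockResult]:
    """One results.csv row per block.

    A train is attributed to the block containing its start; the block's ICI
    min/max/mean pool every individual ICI of those trains. Whistle entries
    (anything with start_s and a W/MW tag) count toward the block containing
    their start, and Multiple W is YES iff any of them is tagged MW.
    """
    rows = []
    for b in range(n_blocks):
        lo, hi = b * block_length_s, (b + 1) * block_length_s
        block_trains = [t for t in trains if lo <= t.start_s < hi]
        block_peaks = sum(1 for p in peaks if lo <= p.time_s < hi)
        pooled = [ici for t in block_trains for ici in t.healed_icis_ms]
        block_whistles = [w for w in whistles if lo <= w.start_s < hi]
        rows.append(BlockResult(
            block_no=b + 1,
            peak_number=block_peaks,
            train_number=len(block_trains),
            ici_min_ms=round(float(np.min(pooled)), 3) if pooled else None,
            ici_max_ms=round(float(np.max(pooled)), 3) if pooled else None,
            ici_mean_ms=round(float(np.mean(pooled)), 3) if pooled else None,
            whistle_count=len(block_whistles),
            multiple_w=any(getattr(w, "tag", None) == "MW" for w in block_whistles),
        ))
    return rows
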