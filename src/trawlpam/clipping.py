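"""Overload (clipping) quantification.

A recorder saturates when a dolphin vocalizes at close range; the flattened
waveform peaks show up as runs of samples at or near the recording's maximum.
The report counts samples whose magnitude reaches a stated fraction of the
signal peak — 99% and 90% by default, the two thresholds used to validate the
study recording. "Signal peak" is the global maximum |sample| of the analyzed
recording (peak-relative); a full-scale-relative variant is available since a
16-bit recorder rails at exactly full scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import Recording


@dataclass
class ClippingReport:
    """Samples at or above threshold_fraction x reference amplitude."""

    threshold_fraction: float
    peak_amplitude: float
    clipped_count: int
    total_count: int

    def __post_init__(self):
        if not (0 <= self.clipped_count <= self.total_count):
            raise ValueError("clipped_count must lie in [0, total_count]")

    @property
    def clipped_percent(self) -> float:
        """Percentage of samples counted as overloaded, to 2 decimals."""
        return round(100.0 * self.clipped_count / self.total_count, 2)


def clipped_fraction(
    recording: Recording,
    threshold_fraction: float,
    relative_to: str = "peak",
) -> ClippingReport:
    """Count samples with |s| >= threshold_fraction x reference.

    ``relative_to="peak"`` uses the recording's own maximum |sample| (the
    study's reading of "signal peak"); ``"full_scale"`` uses 1.0. The
    comparison is >= (not >) so exact-full-scale samples are counted.
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1]")
    s = np.abs(recording.samples)
    peak = float(s.max())
    if relative_to == "peak":
        ref = peak
    elif relative_to == "full_scale":
        ref = 1.0
    else:
        raise ValueError("relative_to must be 'peak' or 'full_scale'")
    count = int(np.count_nonzero(s >= threshold_fraction * ref))
    return ClippingReport(threshold_fraction, peak, count, s.size)


def overload_percentages(
    recording: Recording,
    relative_to: str = "peak",
) -> tuple[ClippingReport, ClippingReport]:
    """The study's pair of reports: thresholds 0.99 and 0.90 of the peak."""
    return (
        clipped_fraction(recording, 0.99, relative_to),
        clipped_fraction(recording, 0.90, relative_to),
    )
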