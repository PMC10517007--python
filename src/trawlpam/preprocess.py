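"""High-pass noise filtering and fixed-length block segmentation.

The analysis removes vessel noise (propeller, engine) with an 8th-order
Butterworth high-pass at 10 kHz (-48 dB/octave one-pass roll-off) and then
splits the recording into consecutive 60-s blocks, keeping the final partial
block. Filtering defaults to zero-phase (forward-backward) application so
click times are not phase-delayed; this doubles the effective roll-off, and a
``zero_phase=False`` flag restores one-pass behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .formats import Recording


@dataclass
class FilterSpec:
    """Butterworth high-pass design: order and cutoff."""

    order: int = 8
    cutoff_hz: float = 10000.0
    kind: str = "highpass"

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")

    def design(self, sample_rate: int) -> np.ndarray:
        """Second-order sections for this design at a given rate."""
        if self.cutoff_hz >= sample_rate / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must be below Nyquist ({sample_rate / 2} Hz)"
            )
        return signal.butter(self.order, self.cutoff_hz, self.kind,
                             fs=sample_rate, output="sos")


@dataclass
class BlockSet:
    """Consecutive fixed-length blocks of one recording (last may be partial)."""

    blocks: list[Recording]
    block_length_s: float

    @property
    def last_block_length_s(self) -> float:
        return self.blocks[-1].duration_s

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def concatenate(self) -> Recording:
        first = self.blocks[0]
        return Recording(
            np.concatenate([b.samples for b in self.blocks]),
            first.sample_rate, first.bit_depth, first.start_offset,
        )


def highpass(recording: Recording, spec: FilterSpec = FilterSpec(),
             zero_phase: bool = True) -> Recording:
    """Apply the Butterworth high-pass; output length equals input length."""
    sos = spec.design(recording.sample_rate)
    warmup = 3 * (2 * sos.shape[0] + 1)
    if recording.samples.size <= warmup:
        raise ValueError(
            f"recording of {recording.samples.size} samples is shorter than the "
            f"filter warm-up ({warmup} samples for order {spec.order})"
        )
    if zero_phase:
        y = signal.sosfiltfilt(sos, recording.samples)
    else:
        y = signal.sosfilt(sos, recording.samples)
    y = np.clip(y, -1.0, 1.0)  # filter ringing can overshoot full scale marginally
    return Recording(y, recording.sample_rate, recording.bit_depth, recording.start_offset)


def split_blocks(recording: Recording, block_length_s: float = 60.0) -> BlockSet:
    """Split into consecutive non-overlapping blocks, keeping the partial tail.

    Each block's ``start_offset`` is its position on the original clock, so
    event times remain absolute downstream.
    """
    if block_length_s <= 0:
        raise ValueError("block_length_s must be positive")
    fs = recording.sample_rate
    n_block = int(round(block_length_s * fs))
    blocks = []
    for i, i0 in enumerate(range(0, recording.samples.size, n_block)):
        chunk = recording.samples[i0:i0 + n_block]
        blocks.append(Recording(
            chunk, fs, recording.bit_depth,
            recording.start_offset + i * block_length_s,
        ))
    return BlockSet(blocks, block_length_s)
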