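"""Readers and writers for the on-disk artifacts of a trawl-recording analysis.

The analysis exchanges four kinds of file: mono PCM WAV audio, tab-separated
label tracks (importable by Audacity), a per-block ``results.csv`` summary
table, and a folder of sequentially named whistle segment WAVs. All audio is
held in memory as float samples normalized to full scale, i.e. in [-1, +1];
normalization is ratio-preserving, so SNR and clipping quantities are
unaffected by it. Times are seconds from the start of the original recording,
with half-open intervals [start, end).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.io import wavfile


class FormatError(ValueError):
    """A file does not have the expected layout (names the offending property)."""


class LabelParseError(ValueError):
    """A label-track line could not be parsed (carries the 1-based line number)."""

    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


@dataclass
class Recording:
    """Mono audio held as full-scale-normalized float samples.

    ``start_offset`` is the position of the first sample on the clock of the
    original recording, in seconds (0 for standalone files).
    """

    samples: np.ndarray
    sample_rate: int
    bit_depth: int = 16
    start_offset: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise FormatError(f"expected mono audio, got {self.samples.ndim} dimensions")
        if self.samples.size < 1:
            raise ValueError("a Recording must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        amax = float(np.max(np.abs(self.samples)))
        if amax > 1.0:
            raise ValueError(f"samples must lie in [-1, +1]; max |sample| = {amax:.6g}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def end_offset(self) -> float:
        return self.start_offset + self.duration_s

    def slice_seconds(self, start_s: float, end_s: float) -> "Recording":
        """Cut [start_s, end_s) on the original recording's clock."""
        if start_s < self.start_offset - 1e-9 or end_s > self.end_offset + 1e-9:
            raise ValueError(
                f"segment [{start_s}, {end_s}) s exceeds recording span "
                f"[{self.start_offset}, {self.end_offset}) s"
            )
        i0 = int(round((start_s - self.start_offset) * self.sample_rate))
        i1 = int(round((end_s - self.start_offset) * self.sample_rate))
        i0 = max(i0, 0)
        i1 = min(i1, self.samples.size)
        return Recording(self.samples[i0:i1], self.sample_rate, self.bit_depth, start_s)


@dataclass
class LabelEntry:
    """One line of an Audacity-style label track."""

    start_s: float
    end_s: float
    tag: Optional[str] = None
    quality_class: Optional[int] = None

    def __post_init__(self):
        if not (0.0 <= self.start_s <= self.end_s):
            raise ValueError(
                f"label times must satisfy 0 <= start <= end, got ({self.start_s}, {self.end_s})"
            )
        if self.quality_class is not None and self.quality_class not in (1, 2, 3):
            raise ValueError(f"quality_class must be 1, 2 or 3, got {self.quality_class}")


@dataclass
class BlockResult:
    """Per-block summary row of results.csv.

    ICI fields are None (rendered as empty cells) when the block holds no
    train: zero is a legal interval value and must not stand for absence.
    """

    block_no: int
    peak_number: int
    train_number: int
    ici_min_ms: Optional[float] = None
    ici_max_ms: Optional[float] = None
    ici_mean_ms: Optional[float] = None
    whistle_count: int = 0
    multiple_w: bool = False

    def __post_init__(self):
        if self.block_no < 1:
            raise ValueError("block_no counts from 1")
        if self.train_number >= 1:
            if None in (self.ici_min_ms, self.ici_max_ms, self.ici_mean_ms):
                raise ValueError("blocks with trains must carry ICI min/mean/max")
            if not (self.ici_min_ms <= self.ici_mean_ms <= self.ici_max_ms):
                raise ValueError("ICI fields must satisfy min <= mean <= max")
        elif any(v is not None for v in (self.ici_min_ms, self.ici_max_ms, self.ici_mean_ms)):
            raise ValueError("blocks without trains must leave ICI fields undefined")


# --- WAV ------------------------------------------------------------------

_PCM_SCALE = {np.dtype(np.int16): 2 ** 15, np.dtype(np.int32): 2 ** 31}
_PCM_BITS = {np.dtype(np.int16): 16, np.dtype(np.int32): 32}


def read_wav(path) -> Recording:
    """Read a mono PCM WAV file into a full-scale-normalized Recording.

    Integer PCM values are divided by the full-scale magnitude 2**(bits-1),
    so the most negative code maps exactly to -1.0.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise FormatError(f"{path}: expected 1 channel, file has {data.shape[1]}")
    if data.dtype not in _PCM_SCALE:
        raise FormatError(f"{path}: unsupported sample format {data.dtype} (integer PCM required)")
    scale = _PCM_SCALE[data.dtype]
    return Recording(data.astype(np.float64) / scale, int(rate), _PCM_BITS[data.dtype])


def write_wav(recording: Recording, path) -> None:
    """Write a Recording as mono PCM WAV at its own sample rate and bit depth.

    Samples outside [-1, +1] are rejected, never silently clipped: deliberate
    overload must go through the clipping simulator first.
    """
    s = recording.samples
    amax = float(np.max(np.abs(s)))
    if amax > 1.0:
        raise ValueError(f"samples outside [-1, +1] (max |s| = {amax:.6g}); refusing to clip")
    if recording.bit_depth == 16:
        dtype, scale = np.int16, 2 ** 15
    elif recording.bit_depth == 32:
        dtype, scale = np.int32, 2 ** 31
    else:
        raise FormatError(f"unsupported bit depth {recording.bit_depth}")
    pcm = np.clip(np.rint(s * scale), -scale, scale - 1).astype(dtype)
    wavfile.write(str(path), recording.sample_rate, pcm)


# --- Label tracks ---------------------------------------------------------


def write_label_track(entries: Sequence[LabelEntry], path, kind: str = "whistle") -> None:
    """Write an Audacity-importable tab-separated label track.

    Whistle labels are the tag ("W"/"MW") with the quality class appended
    after a space; click labels are the train's mean-ICI bin label held in
    ``tag``. Times are printed with 6 decimal places.
    """
    if kind not in ("whistle", "click"):
        raise ValueError(f"kind must be 'whistle' or 'click', got {kind!r}")
    starts = [e.start_s for e in entries]
    for i in range(1, len(starts)):
        if starts[i] < starts[i - 1]:
            raise ValueError(
                f"entries must be sorted by start time; first inversion at index {i} "
                f"({starts[i]:.6f} < {starts[i - 1]:.6f})"
            )
    lines = []
    for e in entries:
        label = e.tag or ""
        if kind == "whistle" and e.quality_class is not None:
            label = f"{label} {e.quality_class}"
        lines.append(f"{e.start_s:.6f}\t{e.end_s:.6f}\t{label}")
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_label_track(path) -> list[LabelEntry]:
    """Parse a tab-separated label track back into entries.

    A third column of the form ``"W 2"`` splits into tag and quality class; a
    single token stays the whole tag.
    """
    entries = []
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise LabelParseError("fewer than 2 tab-separated columns", line_no)
        try:
            start_s, end_s = float(fields[0]), float(fields[1])
        except ValueError:
            raise LabelParseError(f"non-numeric time field in {fields[:2]}", line_no) from None
        tag: Optional[str] = None
        quality: Optional[int] = None
        if len(fields) >= 3 and fields[2]:
            parts = fields[2].split(" ")
            if len(parts) == 2 and parts[1].isdigit():
                tag, quality = parts[0], int(parts[1])
            else:
                tag = fields[2]
        try:
            entries.append(LabelEntry(start_s, end_s, tag, quality))
        except ValueError as exc:
            raise LabelParseError(str(exc), line_no) from None
    return entries


# --- results.csv ----------------------------------------------------------

RESULTS_HEADER = [
    "Block#", "Peak number", "Train number",
    "ICImin", "ICImax", "ICImean", "Whistle", "Multiple W",
]


def _fmt(v: Optional[float]) -> str:
    return "" if v is None else str(v)


def write_results_csv(rows: Sequence[BlockResult], path) -> None:
    """Write the per-block summary table with the deposit's 8 named columns."""
    for i, row in enumerate(rows):
        if row.block_no != i + 1:
            raise ValueError(
                f"block numbers must be consecutive from 1; row {i} has Block# {row.block_no}"
            )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RESULTS_HEADER)
        for r in rows:
            w.writerow([
                r.block_no, r.peak_number, r.train_number,
                _fmt(r.ici_min_ms), _fmt(r.ici_max_ms), _fmt(r.ici_mean_ms),
                r.whistle_count, "YES" if r.multiple_w else "NO",
            ])


def read_results_csv(path) -> list[BlockResult]:
    """Parse results.csv back into BlockResult rows (inverse of the writer)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != RESULTS_HEADER:
            raise FormatError(f"unexpected results.csv header: {header}")
        for rec in reader:
            rows.append(BlockResult(
                block_no=int(rec[0]),
                peak_number=int(rec[1]),
                train_number=int(rec[2]),
                ici_min_ms=float(rec[3]) if rec[3] else None,
                ici_max_ms=float(rec[4]) if rec[4] else None,
                ici_mean_ms=float(rec[5]) if rec[5] else None,
                whistle_count=int(rec[6]),
                multiple_w=rec[7] == "YES",
            ))
    return rows


# --- Whistle segment folder ----------------------------------------------


def export_whistle_segments(recording: Recording, catalog, directory) -> list[Path]:
    """Cut every cataloged whistle to its own WAV under sequential names.

    Files are named 001_whistle.wav, 002_whistle.wav, ... in catalog order,
    matching the deposit's whistle_segments folder layout.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, seg in enumerate(catalog, start=1):
        cut = recording.slice_seconds(seg.start_s, seg.end_s)
        out = directory / f"{i:03d}_whistle.wav"
        write_wav(cut, out)
        paths.append(out)
    return paths
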