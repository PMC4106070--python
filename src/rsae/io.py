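"""Reading, segmenting and splitting multichannel EEG recordings.

A :class:`Recording` is a channels x samples matrix in microvolts with a
sampling rate and a sorted list of half-open seizure intervals in seconds.
Segmentation cuts it into fixed-length windows: nonseizure windows tile the
seizure-free stretches without overlap, seizure windows slide inside each
seizure interval with a configurable overlap, and windows straddling an
interval boundary are discarded so every emitted label is unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

SEIZURE = "seizure"
NONSEIZURE = "nonseizure"


@dataclass
class Recording:
    """Multichannel signal with sampling rate and seizure annotations.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per channel, file order preserved.
    seizure_intervals : list of (float, float)
        Half-open ``[start, end)`` intervals in seconds, sorted and
        non-overlapping, contained in ``[0, duration]``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match channel count")
        ivals = [(float(a), float(b)) for a, b in self.seizure_intervals]
        ivals.sort()
        for a, b in ivals:
            if not (0.0 <= a < b <= self.duration_s + 1e-9):
                raise ValueError(f"interval ({a}, {b}) outside [0, {self.duration_s}] or empty")
        for (a0, b0), (a1, b1) in zip(ivals, ivals[1:]):
            if a1 < b0:
                raise ValueError(f"seizure intervals ({a0},{b0}) and ({a1},{b1}) overlap")
        self.seizure_intervals = ivals

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class Segment:
    """One fixed-length labeled window of multichannel signal."""

    data: np.ndarray          # n_channels x window_samples
    label: str                # SEIZURE or NONSEIZURE
    start_s: float = 0.0      # seconds into the source recording

    def __post_init__(self) -> None:
        if self.label not in (SEIZURE, NONSEIZURE):
            raise ValueError(f"unknown label {self.label!r}")


def read_intervals(path: str | Path) -> list[tuple[float, float]]:
    """Read seizure annotations from a two-column text file of start/end seconds."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.size == 0:
        return []
    if arr.shape[1] != 2:
        raise ValueError(f"annotation file must have two columns, got {arr.shape[1]}")
    return [(float(a), float(b)) for a, b in arr]


def write_intervals(path: str | Path, intervals: Sequence[tuple[float, float]]) -> None:
    with open(path, "w") as fh:
        for a, b in intervals:
            fh.write(f"{a:.6f}\t{b:.6f}\n")


def read_recording(
    path: str | Path,
    format: str = "delimited",
    fs: float | None = None,
    intervals: str | Path | Sequence[tuple[float, float]] | None = None,
) -> Recording:
    """Read a multichannel recording from EDF or delimited numeric text.

    The delimited dialect is one channel per row, whitespace- or
    comma-separated samples; ``fs`` is then required.  EDF files carry their
    own sampling rate (all channels must share it) and are converted from
    volts to microvolts.  ``intervals`` may be a path to a two-column
    start/end annotation file or a sequence of ``(start_s, end_s)`` pairs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(intervals, (str, Path)):
        ivals = read_intervals(intervals)
    else:
        ivals = [tuple(map(float, iv)) for iv in (intervals or [])]

    if format == "delimited":
        if fs is None:
            raise ValueError("fs is required for delimited input")
        text = path.read_text()
        delimiter = "," if ("," in text.splitlines()[0] if text.splitlines() else False) else None
        try:
            data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"could not parse delimited recording {path}: {exc}") from exc
        rate = float(fs)
        labels: list[str] = []
    elif format == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("EDF input requires the 'mne' package (rsae[edf])") from exc
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        sfreqs = {float(raw.info["sfreq"])}
        if len(sfreqs) != 1:  # pragma: no cover - mne resamples mixed-rate files
            raise ValueError("EDF channels have mismatched sampling rates")
        data = raw.get_data() * 1e6  # volts -> microvolts
        rate = float(raw.info["sfreq"])
        labels = list(raw.ch_names)
    else:
        raise ValueError(f"unknown format {format!r}")

    if data.shape[0] < 2:
        raise ValueError(f"need at least 2 channels, got {data.shape[0]}")
    return Recording(data=data, fs=rate, channel_labels=labels, seizure_intervals=ivals)


def write_recording(path: str | Path, rec: Recording, fmt: str = "%.8g") -> None:
    """Write a Recording to the delimited dialect (one channel per row)."""
    np.savetxt(path, rec.data, fmt=fmt, delimiter="\t")


def segment_recording(
    rec: Recording,
    window_s: float = 5.0,
    seizure_overlap_frac: float = 0.5,
    max_per_class: int | None = None,
) -> list[Segment]:
    """Cut a recording into labeled fixed-length windows.

    Nonseizure windows tile each seizure-free stretch with stride equal to
    the window length (no overlap).  Seizure windows slide within each
    seizure interval with stride ``window_s * (1 - seizure_overlap_frac)``.
    A window is emitted only if it lies fully inside one seizure interval
    (label seizure) or fully outside all intervals (label nonseizure).
    """
    if not (0.0 <= seizure_overlap_frac < 1.0):
        raise ValueError("seizure_overlap_frac must be in [0, 1)")
    L = round(window_s * rec.fs)
    if L < 2:
        raise ValueError("window too short: fewer than 2 samples")
    if window_s > rec.duration_s + 1e-9:
        raise ValueError(f"window ({window_s}s) longer than recording ({rec.duration_s:.3f}s)")

    def cut(start_s: float, label: str) -> Segment | None:
        i0 = math.floor(start_s * rec.fs)
        if i0 + L > rec.n_samples:
            return None
        return Segment(data=rec.data[:, i0:i0 + L], label=label, start_s=start_s)

    eps = 1e-9
    segments: list[Segment] = []

    # Nonseizure: tile the gaps between seizure intervals.
    gaps: list[tuple[float, float]] = []
    cursor = 0.0
    for a, b in rec.seizure_intervals:
        if a - cursor > eps:
            gaps.append((cursor, a))
        cursor = b
    if rec.duration_s - cursor > eps:
        gaps.append((cursor, rec.duration_s))
    n_nonseiz = 0
    for a, b in gaps:
        start = a
        while start + window_s <= b + eps:
            seg = cut(start, NONSEIZURE)
            if seg is not None and (max_per_class is None or n_nonseiz < max_per_class):
                segments.append(seg)
                n_nonseiz += 1
            start += window_s

    # Seizure: slide within each interval with the configured overlap.
    stride = window_s * (1.0 - seizure_overlap_frac)
    n_seiz = 0
    for a, b in rec.seizure_intervals:
        start = a
        while start + window_s <= b + eps:
            seg = cut(start, SEIZURE)
            if seg is not None and (max_per_class is None or n_seiz < max_per_class):
                segments.append(seg)
                n_seiz += 1
            start += stride

    if rec.seizure_intervals and n_seiz == 0:
        raise ValueError("no seizure window fits inside any annotated interval")
    if n_nonseiz == 0:
        raise ValueError("no nonseizure window fits outside the annotated intervals")
    return segments


def split_train_test(
    segments: Sequence[Segment],
    n_train_per_class: int = 750,
    seed: int = 0,
) -> tuple[list[Segment], list[Segment]]:
    """Seeded per-class split: exactly ``n_train_per_class`` of each label
    into the training set (sampled without replacement), remainder to test."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {SEIZURE: [], NONSEIZURE: []}
    for i, seg in enumerate(segments):
        by_class[seg.label].append(i)
    train_idx: list[int] = []
    for label in (SEIZURE, NONSEIZURE):
        idx = np.array(by_class[label], dtype=int)
        if len(idx) < n_train_per_class:
            raise ValueError(
                f"class {label!r} has {len(idx)} segments, need {n_train_per_class}")
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[:n_train_per_class]].tolist())
    chosen = set(train_idx)
    train = [segments[i] for i in sorted(chosen)]
    test = [segments[i] for i in range(len(segments)) if i not in chosen]
    return train, test
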