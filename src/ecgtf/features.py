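"""Per-heartbeat segmentation and time-frequency feature fusion.

Around each R apex the beat window keeps the n-1 preceding and 2n
following samples (3n total; 300 at n=100, covering P through T and the
onset of the next beat at a normal heart rate).  The window is zero-padded
to ``fft_length`` (the 360 Hz sampling rate by default) before the FFT so
the retained half-spectrum has exactly fft_length/2 = 180 bins at 1 Hz
spacing, covering 0-179 Hz.  Magnitudes are scaled by 2/fft_length so a
unit-amplitude on-bin sinusoid maps to magnitude ~1.  Time samples and
spectrum are concatenated, time part first, into the fused 480-vector fed
to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BEAT_CLASSES, ECGRecord
from .rpeak import RPeakList

__all__ = [
    "HeartbeatSegment",
    "FusedFeature",
    "segment_heartbeat",
    "spectrum",
    "fuse",
    "build_dataset",
]


@dataclass
class HeartbeatSegment:
    """One beat's 3n-sample window; the R apex sits at local offset n-1."""

    samples: np.ndarray
    r_index: int
    label: str | None = None
    fs: float = 360.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size % 3 != 0:
            raise ValueError("segment length must be 3n")
        if self.label is not None and self.label not in BEAT_CLASSES:
            raise ValueError(f"unknown beat class {self.label!r}")

    @property
    def n(self) -> int:
        return self.samples.size // 3


@dataclass
class FusedFeature:
    """Concatenated time||frequency vector for one beat (480 by default)."""

    vector: np.ndarray
    time_len: int
    freq_len: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()
        if self.vector.size != self.time_len + self.freq_len:
            raise ValueError("vector length must equal time_len + freq_len")


def segment_heartbeat(record: ECGRecord | np.ndarray, r_index: int,
                      n: int = 100, label: str | None = None) -> HeartbeatSegment:
    """Extract the n-1 samples before, the R sample, and 2n after (3n total).

    Raises ``ValueError`` for beats whose window leaves the record
    ("incomplete beat"); callers skip those edge beats.
    """
    x = record.samples if isinstance(record, ECGRecord) else np.asarray(record, dtype=float)
    fs = record.fs if isinstance(record, ECGRecord) else 360.0
    if n < 1:
        raise ValueError("n must be >= 1")
    lo = r_index - (n - 1)
    hi = r_index + 2 * n + 1
    if lo < 0 or hi > x.size:
        raise ValueError(
            f"incomplete beat at r_index={r_index}: window [{lo}, {hi}) "
            f"exceeds record of length {x.size}"
        )
    return HeartbeatSegment(x[lo:hi].copy(), r_index=int(r_index), label=label, fs=fs)


def spectrum(segment: HeartbeatSegment | np.ndarray, fft_length: int = 360,
             scale: bool = True) -> np.ndarray:
    """First fft_length/2 DFT magnitudes of the zero-padded beat.

    Only the first half of the spectrum is kept (it is conjugate-symmetric
    for real input): bins 0..fft_length/2 - 1, i.e. 0-179 Hz at 1 Hz
    resolution for a 360-point transform of a 360 Hz signal.  With
    ``scale`` the magnitudes are multiplied by 2/fft_length.
    """
    x = segment.samples if isinstance(segment, HeartbeatSegment) else np.asarray(segment, dtype=float)
    if fft_length < x.size:
        raise ValueError(
            f"fft_length {fft_length} would truncate a {x.size}-sample segment"
        )
    mags = np.abs(np.fft.rfft(x, n=fft_length))[: fft_length // 2]
    if scale:
        mags = mags * (2.0 / fft_length)
    return mags


def fuse(segment: HeartbeatSegment, spec: np.ndarray) -> FusedFeature:
    """Concatenate time samples then spectrum; label carried from segment."""
    spec = np.asarray(spec, dtype=float).ravel()
    return FusedFeature(
        vector=np.concatenate([segment.samples, spec]),
        time_len=segment.samples.size,
        freq_len=spec.size,
        label=segment.label,
    )


def build_dataset(record: ECGRecord, peaks: RPeakList | np.ndarray | None = None,
                  n: int = 100, fft_length: int = 360,
                  labels: list[str] | None = None,
                  scale: bool = True) -> tuple[list[FusedFeature], int]:
    """Fused features for every complete beat of one record.

    ``peaks`` defaults to the record's annotations (training path); pass a
    detected :class:`RPeakList` for the deployment path.  ``labels``
    parallels ``peaks``; when peaks come from annotations the annotation
    labels are used.  Returns (features, n_skipped) where n_skipped counts
    incomplete edge beats.
    """
    if peaks is None:
        if record.ann_indices is None:
            raise ValueError("record has no annotations; supply peaks explicitly")
        idx = record.ann_indices
        if labels is None:
            labels = record.ann_labels
    else:
        idx = peaks.indices if isinstance(peaks, RPeakList) else np.asarray(peaks, dtype=np.int64)
    if labels is not None and len(labels) != len(idx):
        raise ValueError("labels must parallel peak indices")

    feats: list[FusedFeature] = []
    skipped = 0
    for k, r in enumerate(idx):
        lab = labels[k] if labels is not None else None
        try:
            seg = segment_heartbeat(record, int(r), n=n, label=lab)
        except ValueError:
            skipped += 1
            continue
        feats.append(fuse(seg, spectrum(seg, fft_length=fft_length, scale=scale)))
    return feats, skipped
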