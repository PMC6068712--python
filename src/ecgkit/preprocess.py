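"""Preprocessing: resampling to 300 Hz, band-pass filtering, normalization,
and overlapped segmentation into 8 s analysis windows.

The pipeline mirrors common ambulatory-ECG practice: resample to a fixed
working rate, suppress baseline drift and high-frequency noise with a
third-order 0.4-30 Hz Butterworth band-pass (applied forward-backward so QRS
morphology is not phase-distorted), then cut 8 s windows advanced by 5 s
(3 s overlap) and standardise each window to zero mean and unit variance.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, DegenerateSignalError, TooShortError
from .records import SEGMENT_SECONDS, TARGET_FS, Segment, EcgRecord

__all__ = [
    "resample_to_300",
    "bandpass",
    "normalize",
    "segment",
    "preprocess_record",
]


def resample_to_300(record: EcgRecord) -> EcgRecord:
    """Resample a record to the 300 Hz working rate (polyphase; no-op at 300 Hz)."""
    if record.fs == TARGET_FS:
        return record
    frac = Fraction(TARGET_FS / record.fs).limit_denominator(10000)
    out = sps.resample_poly(record.samples, frac.numerator, frac.denominator)
    n_out = int(round(len(record) * TARGET_FS / record.fs))
    out = out[:n_out]
    if out.size < n_out:  # pad the odd trailing sample polyphase may drop
        out = np.pad(out, (0, n_out - out.size), mode="edge")
    return EcgRecord(samples=out, fs=TARGET_FS, record_id=record.record_id)


def bandpass(record: EcgRecord, low: float = 0.4, high: float = 30.0, order: int = 3) -> EcgRecord:
    """Third-order Butterworth band-pass, zero-phase (filtfilt)."""
    if record.fs <= 2 * high:
        raise ConfigurationError(
            f"sampling rate {record.fs} Hz must exceed twice the upper band edge {high} Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=record.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, record.samples)
    return EcgRecord(samples=filtered, fs=record.fs,
                     annotations=list(record.annotations), record_id=record.record_id)


def normalize(samples: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance (population 1/N variance) standardisation."""
    x = np.asarray(samples, dtype=float)
    sd = x.std()  # population
    if sd == 0:
        raise DegenerateSignalError("constant signal cannot be normalized")
    return (x - x.mean()) / sd


def segment(
    record: EcgRecord,
    seg_len_s: float = SEGMENT_SECONDS,
    overlap_s: float = 3.0,
) -> list[Segment]:
    """Cut a 300 Hz record into overlapped, individually normalized windows.

    Windows start at multiples of ``seg_len_s - overlap_s`` seconds; the count
    is ``floor((L - seg_len)/step) + 1``.  Each window is normalized after
    cutting, so every emitted segment is exactly zero-mean / unit-variance.
    """
    if record.fs != TARGET_FS:
        raise ConfigurationError("segment() expects a 300 Hz record; resample first")
    if overlap_s >= seg_len_s:
        raise ConfigurationError("overlap must be smaller than the window length")
    n_win = int(round(seg_len_s * record.fs))
    step = int(round((seg_len_s - overlap_s) * record.fs))
    if len(record) < n_win:
        raise TooShortError(
            f"record of {len(record) / record.fs:.2f} s shorter than one {seg_len_s} s window"
        )
    out: list[Segment] = []
    for start in range(0, len(record) - n_win + 1, step):
        window = record.samples[start : start + n_win]
        out.append(Segment(samples=normalize(window), fs=record.fs, start_s=start / record.fs))
    return out


def preprocess_record(
    record: EcgRecord,
    seg_len_s: float = SEGMENT_SECONDS,
    overlap_s: float = 3.0,
    low: float = 0.4,
    high: float = 30.0,
    order: int = 3,
) -> list[Segment]:
    """Full preprocessing chain: resample -> band-pass -> segment + normalize."""
    rec = resample_to_300(record)
    rec = bandpass(rec, low=low, high=high, order=order)
    return segment(rec, seg_len_s=seg_len_s, overlap_s=overlap_s)
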