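"""Core data containers: ECG records, analysis segments, beats, RR series.

All containers are plain frozen-ish dataclasses around numpy arrays; they
validate their own invariants on construction so downstream feature code can
assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EcgKitError

#: Working sampling rate of the whole pipeline (Hz).
TARGET_FS = 300
#: Analysis window length (s) and sample count at TARGET_FS.
SEGMENT_SECONDS = 8
SEGMENT_SAMPLES = TARGET_FS * SEGMENT_SECONDS  # 2400
#: Beat window geometry: samples kept left/right of the R sample.
BEAT_PRE = 70
BEAT_POST = 129
BEAT_SAMPLES = BEAT_PRE + 1 + BEAT_POST  # 200


@dataclass
class EcgRecord:
    """A uniformly sampled single-lead ECG.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence (mV for raw records; unitless after normalization).
    fs : float
        Sampling rate in Hz, > 0.
    annotations : list of (int, str), optional
        Beat / rhythm marks as (sample_index, label).
    record_id : str
        Free-text identifier (file stem, database record name, ...).
    """

    samples: np.ndarray
    fs: float
    annotations: list[tuple[int, str]] = field(default_factory=list)
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise EcgKitError("EcgRecord requires a non-empty 1-D sample array")
        if not self.fs > 0:
            raise EcgKitError(f"sampling rate must be positive, got {self.fs}")
        for idx, _label in self.annotations:
            if not 0 <= idx < self.samples.size:
                raise EcgKitError(f"annotation index {idx} outside record")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class Segment:
    """One preprocessed 8 s analysis window (2400 samples at 300 Hz).

    Samples are zero-mean / unit-variance; ``start_s`` is the window's offset
    in the source record.
    """

    samples: np.ndarray
    fs: float = TARGET_FS
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = int(round(self.fs * SEGMENT_SECONDS))
        if self.samples.size != expected:
            raise EcgKitError(
                f"segment must hold exactly {expected} samples, got {self.samples.size}"
            )

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class Beat:
    """A 200-sample beat window with the R sample at index 70."""

    samples: np.ndarray
    r_offset: int = BEAT_PRE
    source: tuple[int, int] | None = None  # (segment index, R sample index)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size != BEAT_SAMPLES:
            raise EcgKitError(
                f"beat must hold exactly {BEAT_SAMPLES} samples, got {self.samples.size}"
            )
        if self.r_offset != BEAT_PRE:
            raise EcgKitError(f"beat R offset must be {BEAT_PRE}")


@dataclass
class RrSeries:
    """Successive R-to-R intervals (s) plus the R-peak sample indices."""

    rr: np.ndarray
    r_indices: np.ndarray
    fs: float = TARGET_FS

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.r_indices = np.asarray(self.r_indices, dtype=int)
        if np.any(self.rr <= 0):
            raise EcgKitError("RR intervals must be positive")

    @classmethod
    def from_peaks(cls, r_indices, fs: float = TARGET_FS) -> "RrSeries":
        r = np.asarray(r_indices, dtype=int)
        return cls(rr=np.diff(r) / fs, r_indices=r, fs=fs)

    def __len__(self) -> int:
        return self.rr.size
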