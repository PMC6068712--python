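"""Beat-level PVC features.

Beats are 200-sample windows (70 samples left of the R point, 129 right),
covering the full PQRST complex at 300 Hz even for the widened QRS of a
PVC.  Four features discriminate PVC from normal beats:

* LMMD - peak-to-valley amplitude of the window (PVCs are larger);
* MSA  - maximum single-sided spectral amplitude of the beat (the wide,
  large PVC complex concentrates more low-frequency power);
* WSE  - normalized Shannon entropy of the wavelet coefficient energies;
* Kurt - population (non-excess) kurtosis of the beat samples.
"""

from __future__ import annotations

import numpy as np
import pywt

from .errors import DegenerateSignalError
from .records import BEAT_POST, BEAT_PRE, Beat, Segment
from .spectral import amplitude_spectrum

__all__ = [
    "segment_beats",
    "lmmd",
    "msa",
    "wavelet_shannon_entropy",
    "kurtosis",
]

WAVELET = "db4"
WAVELET_LEVEL = 4


def segment_beats(segment: Segment, r_indices, segment_id: int = 0) -> list[Beat]:
    """Cut [r-70, r+129] beat windows around each R index.

    Beats whose window would cross a segment boundary are skipped (padding
    would distort the spectral features); the skip count is simply
    ``len(r_indices) - len(result)``.
    """
    x = segment.samples
    beats: list[Beat] = []
    for r in np.asarray(r_indices, dtype=int):
        lo, hi = r - BEAT_PRE, r + BEAT_POST + 1
        if lo < 0 or hi > x.size:
            continue
        beats.append(Beat(samples=x[lo:hi], source=(segment_id, int(r))))
    return beats


def _samples(beat) -> np.ndarray:
    return beat.samples if isinstance(beat, Beat) else np.asarray(beat, dtype=float)


def lmmd(beat) -> float:
    """Local maxima-minima difference: max - min of the beat window."""
    x = _samples(beat)
    return float(x.max() - x.min())


def msa(beat, fs: float = 300.0) -> float:
    """Maximum single-sided spectral amplitude of the beat (raw amplitudes).

    The spectrum is deliberately not max-normalized - that would make this
    feature identically 1.  MSA therefore scales linearly with amplitude.
    """
    spec = amplitude_spectrum(_samples(beat), fs=fs, normalize=False)
    return float(spec.amps.max())


def wavelet_shannon_entropy(beat, wavelet: str = WAVELET, level: int = WAVELET_LEVEL) -> float:
    """Normalized Shannon entropy of the wavelet coefficient energy distribution.

    A ``level``-level Daubechies-4 decomposition of the beat; p_i is the
    energy fraction of coefficient i over all approximation and detail
    coefficients, and the entropy is normalized by log2 of the coefficient
    count, giving a value in [0, 1].  Impulsive beats concentrate energy in
    few coefficients (low WSE); noise spreads it (high WSE).
    """
    x = _samples(beat)
    coeffs = np.concatenate(pywt.wavedec(x, wavelet, level=level))
    energy = coeffs ** 2
    total = energy.sum()
    if total == 0:
        raise DegenerateSignalError("all-zero beat has no wavelet energy")
    p = energy[energy > 0] / total
    h = -np.sum(p * np.log2(p))
    return float(h / np.log2(coeffs.size))


def kurtosis(beat) -> float:
    """Population (non-excess) kurtosis E[(X-mu)^4] / E[(X-mu)^2]^2.

    A normal sample gives ~3; the minimum over any distribution is 1
    (attained by a symmetric two-point distribution).
    """
    x = _samples(beat)
    mu = x.mean()
    m2 = np.mean((x - mu) ** 2)
    if m2 == 0:
        raise DegenerateSignalError("constant beat has undefined kurtosis")
    return float(np.mean((x - mu) ** 4) / m2 ** 2)
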