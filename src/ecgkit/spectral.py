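"""Spectral and entropy features shared by the VF and PVC stages.

For an 8 s window at 300 Hz the FFT length equals the 2400-point window, so
the single-sided amplitude spectrum has 0.125 Hz resolution.  F5 counts
spectral bins above the mean amplitude (organized rhythms spread harmonic
energy across many bins; VF concentrates it); F6 is the normalized Shannon
entropy of the amplitude histogram (VF's diffuse amplitude distribution has
higher entropy than the spiky NSR distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, EcgKitError

__all__ = [
    "AmplitudeSpectrum",
    "amplitude_spectrum",
    "f5_count_above_mean",
    "shannon_entropy",
    "f6_shannon_entropy",
]

DEFAULT_ENTROPY_BINS = 16


@dataclass
class AmplitudeSpectrum:
    """Single-sided amplitude spectrum, normalized to unit maximum."""

    freqs: np.ndarray
    amps: np.ndarray
    df: float


def amplitude_spectrum(
    samples: np.ndarray, fs: float, nfft: int | None = None, normalize: bool = True
) -> AmplitudeSpectrum:
    """Single-sided amplitude spectrum with nfft defaulting to the data length.

    With ``normalize`` the amplitudes are scaled to unit maximum (the form
    the VF feature F5 consumes); with ``normalize=False`` raw single-sided
    amplitudes (2|X|/N, DC and Nyquist unhalved) are returned, which the
    beat-level MSA feature requires.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise EcgKitError("need at least 2 samples for a spectrum")
    if not np.any(x):
        raise DegenerateSignalError("all-zero signal has no spectrum")
    n = int(nfft) if nfft is not None else x.size
    spec = np.abs(np.fft.rfft(x, n=n))
    amps = 2.0 * spec / n
    amps[0] /= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    if normalize:
        amps = amps / amps.max()
    return AmplitudeSpectrum(freqs=freqs, amps=amps, df=fs / n)


def f5_count_above_mean(spec: AmplitudeSpectrum, f_max: float | None = None) -> int:
    """Count bins whose amplitude strictly exceeds the mean amplitude.

    The mean and the count both range over the whole single-sided spectrum
    (optionally truncated at ``f_max``).
    """
    amps = spec.amps if f_max is None else spec.amps[spec.freqs <= f_max]
    return int(np.sum(amps > amps.mean()))


def shannon_entropy(values: np.ndarray, n_bins: int = DEFAULT_ENTROPY_BINS) -> float:
    """Normalized Shannon entropy of an amplitude histogram, in [0, 1].

    H = -sum p_i log2 p_i over an ``n_bins`` histogram spanning the data
    range, divided by log2(n_bins).  Constant input occupies a single bin and
    returns 0.  Invariant under affine rescaling of the values.
    """
    x = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise EcgKitError("need at least 2 histogram bins")
    if x.min() == x.max():
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    p = counts[counts > 0] / x.size
    h = -np.sum(p * np.log2(p))
    return float(h / np.log2(n_bins))


def f6_shannon_entropy(samples: np.ndarray, n_bins: int = DEFAULT_ENTROPY_BINS) -> float:
    """Normalized Shannon entropy of a segment's amplitude distribution."""
    x = np.asarray(samples, dtype=float)
    if x.size < n_bins:
        raise EcgKitError("segment shorter than the histogram bin count")
    return shannon_entropy(x, n_bins=n_bins)
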