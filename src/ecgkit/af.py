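"""AF-stage features: R-peak detection, RR cleaning, and the three
RR-irregularity statistics (Shannon entropy, turning point ratio, RMSSD).

AF is "irregularly irregular": successive RR intervals behave almost like an
iid draw, which pushes all three statistics up relative to sinus rhythm.
Premature (ectopic) intervals are excluded before the statistics are
computed so a run of PVCs is not mistaken for AF.

The R-peak detector is a Pan-Tompkins-style pipeline (derivative, squaring,
moving-window integration, adaptive thresholding with a 200 ms refractory
period) operating on the already band-passed, normalized segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InsufficientBeatsError
from .records import Segment, RrSeries
from .spectral import shannon_entropy

__all__ = [
    "AfFeatureVector",
    "detect_r_peaks",
    "clean_rr",
    "rmssd_norm",
    "turning_point_ratio",
    "rr_shannon_entropy",
    "af_features",
]

#: Physiologic RR guard band (s): outside this an interval is artefactual.
RR_MIN_S = 0.2
RR_MAX_S = 3.0
#: Relative deviation from the running median beyond which an RR interval
#: is treated as ectopic and excluded.
ECTOPIC_DEVIATION = 0.30
#: Minimum detected peaks for an 8 s segment to enter AF classification.
MIN_PEAKS = 5


@dataclass
class AfFeatureVector:
    """Stage-2 feature vector: all three statistics see only RR intervals."""

    se_rr: float    # normalized Shannon entropy of RR, in [0, 1]
    tpr: float      # turning point ratio, in [0, 1]
    rmssd_n: float  # RMSSD / mean RR, >= 0
    n_beats: int = 0
    ok: bool = True  # False => segment unclassifiable (too few beats)

    def as_array(self) -> np.ndarray:
        return np.array([self.se_rr, self.tpr, self.rmssd_n])


def detect_r_peaks(segment: Segment | np.ndarray, fs: float = 300.0,
                   refractory_s: float = 0.2) -> np.ndarray:
    """Detect R-peak sample indices with a Pan-Tompkins-style pipeline.

    Derivative -> squaring -> 150 ms moving-window integration -> adaptive
    signal/noise threshold (initialized from the first 2 s), with candidate
    peaks at least ``refractory_s`` apart.  Each accepted detection is
    refined to the local maximum of the raw segment within +/-75 ms.
    Returns a strictly increasing index array; empty when nothing crosses
    threshold (flat or degenerate input).
    """
    if isinstance(segment, Segment):
        x, fs = segment.samples, segment.fs
    else:
        x = np.asarray(segment, dtype=float)
    if x.size < int(fs):
        return np.array([], dtype=int)
    # five-point derivative emphasises QRS slopes
    deriv = np.convolve(x, np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0), mode="same")
    sq = deriv ** 2
    win = max(1, int(round(0.15 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")
    if mwi.max() <= 0:
        return np.array([], dtype=int)

    init = mwi[: int(2 * fs)]
    spki = 0.6 * float(init.max())
    npki = float(np.mean(init)) * 0.5
    threshold = npki + 0.25 * (spki - npki)

    distance = max(1, int(round(refractory_s * fs)))
    candidates, _ = sps.find_peaks(mwi, distance=distance)
    accepted: list[int] = []
    for p in candidates:
        if mwi[p] > threshold:
            accepted.append(int(p))
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
        threshold = npki + 0.25 * (spki - npki)

    # refine each detection to the raw-signal maximum nearby (R is the
    # dominant positive deflection in a lead-II-like signal)
    half = int(round(0.075 * fs))
    refined: list[int] = []
    for p in accepted:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    # deduplicate refinements closer than the refractory period
    refined = sorted(set(refined))
    out: list[int] = []
    for r in refined:
        if out and r - out[-1] < distance:
            if x[r] > x[out[-1]]:
                out[-1] = r
        else:
            out.append(r)
    return np.array(out, dtype=int)


def clean_rr(series: RrSeries) -> RrSeries:
    """Exclude non-physiologic and ectopic RR intervals.

    Drops intervals outside [0.2, 3] s, then intervals deviating more than
    30% from the centered running median of 5.  Raises when fewer than 3
    intervals survive.
    """
    rr = np.asarray(series.rr, dtype=float)
    if rr.size < 3:
        raise InsufficientBeatsError("need at least 3 RR intervals")
    rr = rr[(rr >= RR_MIN_S) & (rr <= RR_MAX_S)]
    if rr.size >= 3:
        med = np.empty_like(rr)
        for i in range(rr.size):
            lo, hi = max(0, i - 2), min(rr.size, i + 3)
            med[i] = np.median(rr[lo:hi])
        rr = rr[np.abs(rr - med) <= ECTOPIC_DEVIATION * med]
    if rr.size < 3:
        raise InsufficientBeatsError("fewer than 3 RR intervals after cleaning")
    return RrSeries(rr=rr, r_indices=series.r_indices, fs=series.fs)


def rmssd_norm(rr: np.ndarray) -> float:
    """Root mean square of successive RR differences, divided by mean RR."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise InsufficientBeatsError("need at least 2 RR intervals for RMSSD")
    return float(np.sqrt(np.mean(np.diff(rr) ** 2)) / np.mean(rr))


def turning_point_ratio(rr: np.ndarray) -> float:
    """Fraction of interior RR points that are strict local extrema.

    Equal neighbours do not produce a turning point.  For an iid random
    sequence the expected ratio is 2/3; monotone sequences give 0 and
    strictly alternating ones give 1.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise InsufficientBeatsError("need at least 3 RR intervals for TPR")
    a, b, c = rr[:-2], rr[1:-1], rr[2:]
    turns = ((b > a) & (b > c)) | ((b < a) & (b < c))
    return float(np.sum(turns) / (rr.size - 2))


def rr_shannon_entropy(rr: np.ndarray, n_bins: int = 16) -> float:
    """Normalized histogram Shannon entropy of the RR intervals."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < n_bins / 2:
        raise InsufficientBeatsError(
            f"need at least {n_bins // 2} RR intervals for a {n_bins}-bin entropy"
        )
    return shannon_entropy(rr, n_bins=n_bins)


def af_features(segment: Segment, min_peaks: int = MIN_PEAKS) -> AfFeatureVector:
    """Compute the stage-2 feature vector (SE, TPR, RMSSD) for one segment.

    Segments yielding fewer than ``min_peaks`` detections, or fewer than 3
    cleaned intervals, are flagged unclassifiable (``ok=False``, NaN
    features) rather than dropped.  The entropy bin count is capped at twice
    the available interval count so short windows stay computable; with the
    usual >= 8 intervals of an 8 s window the default 16 bins apply.
    """
    r = detect_r_peaks(segment)
    if r.size < min_peaks:
        return AfFeatureVector(np.nan, np.nan, np.nan, n_beats=int(r.size), ok=False)
    try:
        series = clean_rr(RrSeries.from_peaks(r, fs=segment.fs))
        rr = series.rr
        n_bins = int(min(16, 2 * rr.size))
        return AfFeatureVector(
            se_rr=rr_shannon_entropy(rr, n_bins=n_bins),
            tpr=turning_point_ratio(rr),
            rmssd_n=rmssd_norm(rr),
            n_beats=int(r.size),
            ok=True,
        )
    except InsufficientBeatsError:
        return AfFeatureVector(np.nan, np.nan, np.nan, n_beats=int(r.size), ok=False)
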