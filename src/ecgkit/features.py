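"""Scikit-learn transformers wrapping the per-stage feature extractors.

Each transformer is stateless (``fit`` only validates and records the input
width) and maps raw signal windows to the stage's feature matrix, so the
classifiers compose with sklearn pipelines and model selection:

* :class:`VfFeatureExtractor`: (n, 2400) segments -> (n, 6) F1..F6
* :class:`AfFeatureExtractor`: (n, 2400) segments -> (n, 3) SE/TPR/RMSSD
  (rows of NaN mark unclassifiable segments)
* :class:`BeatFeatureExtractor`: (n, 200) beats -> (n, 4) LMMD/MSA/WSE/Kurt
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import beats as _beats
from .af import af_features
from .phaseplot import DEFAULT_EXTENT, DEFAULT_RESOLUTION, MIN_LINE_LEN, vf_image_features
from .records import BEAT_SAMPLES, SEGMENT_SAMPLES, Segment
from .spectral import (
    DEFAULT_ENTROPY_BINS,
    amplitude_spectrum,
    f5_count_above_mean,
    f6_shannon_entropy,
)

__all__ = ["VfFeatureExtractor", "AfFeatureExtractor", "BeatFeatureExtractor"]


def _as_matrix(X, width: int) -> np.ndarray:
    if isinstance(X, Segment):
        X = [X]
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], Segment):
        X = np.stack([s.samples for s in X])
    X = check_array(X, dtype=float, ensure_2d=True)
    if X.shape[1] != width:
        raise ValueError(f"expected rows of {width} samples, got {X.shape[1]}")
    return X


class _StatelessExtractor(BaseEstimator, TransformerMixin):
    _width = SEGMENT_SAMPLES
    feature_names: tuple[str, ...] = ()

    def fit(self, X, y=None):
        X = _as_matrix(X, self._width)
        self.n_features_in_ = X.shape[1]
        return self

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names, dtype=object)

    def transform(self, X):
        check_is_fitted(self)
        X = _as_matrix(X, self._width)
        return np.array([self._row(row) for row in X])

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)

    def _row(self, row: np.ndarray) -> list[float]:  # pragma: no cover
        raise NotImplementedError


class VfFeatureExtractor(_StatelessExtractor):
    """Stage-1 features F1-F6 of 8 s (2400-sample) segments."""

    feature_names = ("F1", "F2", "F3", "F4", "F5", "F6")

    def __init__(
        self,
        resolution: int = DEFAULT_RESOLUTION,
        extent: tuple[float, float] = DEFAULT_EXTENT,
        min_line_len: int = MIN_LINE_LEN,
        lines_on: str = "lag1",
        entropy_bins: int = DEFAULT_ENTROPY_BINS,
        f5_max_freq: float | None = None,
        fs: float = 300.0,
    ):
        self.resolution = resolution
        self.extent = extent
        self.min_line_len = min_line_len
        self.lines_on = lines_on
        self.entropy_bins = entropy_bins
        self.f5_max_freq = f5_max_freq
        self.fs = fs

    def _row(self, row: np.ndarray) -> list[float]:
        img = vf_image_features(
            row, resolution=self.resolution, extent=self.extent,
            min_line_len=self.min_line_len, lines_on=self.lines_on,
        )
        spec = amplitude_spectrum(row, fs=self.fs)
        f5 = f5_count_above_mean(spec, f_max=self.f5_max_freq)
        f6 = f6_shannon_entropy(row, n_bins=self.entropy_bins)
        return [img.f1, img.f2, img.f3, img.f4, f5, f6]


class AfFeatureExtractor(_StatelessExtractor):
    """Stage-2 RR-interval features of 8 s segments.

    Unclassifiable segments (too few beats) yield NaN rows; use
    ``np.isfinite`` on the output to filter, or inspect
    :func:`ecgkit.af.af_features` directly for the flag and beat count.
    """

    feature_names = ("SE", "TPR", "RMSSD")

    def __init__(self, min_peaks: int = 5, fs: float = 300.0):
        self.min_peaks = min_peaks
        self.fs = fs

    def _row(self, row: np.ndarray) -> list[float]:
        fv = af_features(Segment(samples=row, fs=self.fs), min_peaks=self.min_peaks)
        return [fv.se_rr, fv.tpr, fv.rmssd_n]


class BeatFeatureExtractor(_StatelessExtractor):
    """Stage-3 features of 200-sample beat windows."""

    _width = BEAT_SAMPLES
    feature_names = ("LMMD", "MSA", "WSE", "Kurt")

    def __init__(self, wavelet: str = "db4", level: int = 4, fs: float = 300.0):
        self.wavelet = wavelet
        self.level = level
        self.fs = fs

    def _row(self, row: np.ndarray) -> list[float]:
        return [
            _beats.lmmd(row),
            _beats.msa(row, fs=self.fs),
            _beats.wavelet_shannon_entropy(row, wavelet=self.wavelet, level=self.level),
            _beats.kurtosis(row),
        ]
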