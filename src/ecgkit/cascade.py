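"""The four-stage arrhythmia discrimination cascade.

Each 8 s segment passes through a strict decision chain:

1. VF vs non-VF, on the six image/spectral/entropy features (a lethal
   rhythm is flagged first and stops the chain);
2. AF vs non-AF, on the RR-interval statistics;
3. per-beat PVC vs N classification;
4. the PVC pattern grammar, emitting an episode code (1-7).

Segments whose R-peak detection yields too few beats are flagged
``unclassifiable`` and carried through in the output, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .af import MIN_PEAKS, af_features, detect_r_peaks
from .beats import segment_beats
from .features import BeatFeatureExtractor, VfFeatureExtractor
from .errors import EcgKitError
from .patterns import classify_episode, episode_name
from .preprocess import preprocess_record
from .records import Segment, EcgRecord

__all__ = ["SegmentResult", "CascadeResult", "ArrhythmiaCascade"]


@dataclass
class SegmentResult:
    """Per-segment cascade outcome."""

    index: int
    start_s: float
    stage: str                       # "VF", "AF", "sinus", "unclassifiable"
    episode_code: int | None = None  # 1-7 for sinus segments, else None
    beat_labels: np.ndarray | None = None

    @property
    def episode(self) -> str | None:
        return episode_name(self.episode_code) if self.episode_code else None


@dataclass
class CascadeResult:
    segments: list[SegmentResult]

    @property
    def vet(self) -> list[int | None]:
        """Vector of episode type; None where a segment stopped before stage 4."""
        return [s.episode_code for s in self.segments]


class ArrhythmiaCascade:
    """Runs trained stage models over a record, segment by segment.

    Parameters
    ----------
    vf_model, af_model, pvc_model
        Fitted binary classifiers with a ``predict`` method (1 = positive
        class: VF / AF / PVC respectively).  Any sklearn classifier or a
        portable JSON model from :mod:`ecgkit.classify` works.
    min_beats : int
        Minimum detected R peaks for stages 2-4.
    """

    def __init__(self, vf_model, af_model, pvc_model, min_beats: int = MIN_PEAKS,
                 overlap_s: float = 3.0):
        self.vf_model = vf_model
        self.af_model = af_model
        self.pvc_model = pvc_model
        self.min_beats = min_beats
        self.overlap_s = overlap_s
        self._vf_extractor = VfFeatureExtractor()
        self._beat_extractor = BeatFeatureExtractor()

    @classmethod
    def fit_synthetic(cls, n_per_class: int = 200, kind: str = "bdt", seed: int = 0,
                      **kwargs) -> "ArrhythmiaCascade":
        """Train all three stage models on synthetic balanced datasets."""
        from .classify import train
        from .synth import gen_dataset

        models = []
        for i, stage in enumerate(("vf", "af", "pvc")):
            data = gen_dataset(stage, n_per_class=n_per_class, seed=seed + i)
            models.append(train(data, kind=kind, seed=seed))
        return cls(*models, **kwargs)

    def predict_segment(self, segment: Segment, index: int = 0) -> SegmentResult:
        """Classify one preprocessed segment through all four stages."""
        vf_row = self._vf_extractor.fit([segment]).transform([segment])
        if int(self.vf_model.predict(vf_row)[0]) == 1:
            return SegmentResult(index=index, start_s=segment.start_s, stage="VF")

        fv = af_features(segment, min_peaks=self.min_beats)
        if not fv.ok:
            return SegmentResult(index=index, start_s=segment.start_s,
                                 stage="unclassifiable")
        if int(self.af_model.predict(fv.as_array()[None, :])[0]) == 1:
            return SegmentResult(index=index, start_s=segment.start_s, stage="AF")

        r = detect_r_peaks(segment)
        beats = segment_beats(segment, r, segment_id=index)
        if len(beats) < 1:
            return SegmentResult(index=index, start_s=segment.start_s,
                                 stage="unclassifiable")
        X = np.stack([b.samples for b in beats])
        labels = self.pvc_model.predict(self._beat_extractor.fit(X).transform(X)).astype(int)
        code = classify_episode(labels)
        return SegmentResult(index=index, start_s=segment.start_s, stage="sinus",
                             episode_code=code, beat_labels=labels)

    def predict_record(self, record: EcgRecord, overlap_s: float | None = None) -> CascadeResult:
        """Preprocess a raw record and classify every segment."""
        overlap = self.overlap_s if overlap_s is None else overlap_s
        segments = preprocess_record(record, overlap_s=overlap)
        if not segments:
            raise EcgKitError("record produced no segments")
        return CascadeResult(
            segments=[self.predict_segment(s, index=i) for i, s in enumerate(segments)]
        )
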