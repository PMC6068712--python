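"""Synthetic single-lead ECG generator with exact ground truth.

Beat-based rhythms are built from a train of Gaussian-bump PQRST templates
at 300 Hz:

* **NSR** - full PQRST morphology, mean RR from the configured heart rate
  with small (<= 2%) Gaussian RR jitter.
* **PVC patterns** (bigeminy, trigeminy, quadrigeminy, couplet, triplet,
  VT) - the scheduled beat sequence follows the repeating 0/1 pattern of
  the episode; PVC beats drop the P bump, double the QRS width and have
  1.6x the peak-to-valley amplitude of a normal beat.
* **AF** - the P bump is removed and successive RR intervals are drawn iid
  uniform on [0.4, 1.2] s (irregularly irregular).
* **VF** - no discrete beats at all: a sum of three amplitude- and
  frequency-drifting 3-7 Hz oscillators with phase noise, emulating the
  disorganized, QRS-free trajectory that fills a phase plot.

Ground truth (R sample indices, per-beat PVC labels, rhythm name) is known
by construction, so every downstream metric is computable without
annotation files.  Template synthesis is transparent and analytically
controllable (beat width and amplitude are direct parameters); it does not
attempt physiologically faithful morphology, multi-lead projection, or
motion artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import LabeledDataset
from .errors import EcgKitError
from .features import AfFeatureExtractor, BeatFeatureExtractor, VfFeatureExtractor
from .preprocess import preprocess_record
from .records import TARGET_FS, Beat, EcgRecord
from . import beats as _beats

__all__ = ["SynthSpec", "SynthTruth", "gen_record", "gen_multirhythm", "gen_dataset",
           "RHYTHMS", "PATTERNS"]

RHYTHMS = ("nsr", "af", "vf", "bg", "tg", "qg", "couplet", "triplet", "vt")

#: Repeating PVC/normal unit of each beat-based rhythm (1 = PVC).
PATTERNS = {
    "nsr": (0,),
    "bg": (1, 0),
    "tg": (1, 0, 0),
    "qg": (1, 0, 0, 0),
    "couplet": (1, 1, 0),
    "triplet": (1, 1, 1, 0),
    "vt": (1,),
    "af": (0,),
}

# Gaussian bumps as (center offset s, width s, amplitude) relative to R
_NORMAL_BUMPS = (
    (-0.17, 0.025, 0.15),   # P
    (-0.025, 0.008, -0.10),  # Q
    (0.0, 0.012, 1.00),      # R
    (0.03, 0.010, -0.25),    # S
    (0.30, 0.060, 0.35),     # T
)
# PVC: no P, QRS bumps twice as wide, peak-to-valley 1.6x (2.0 vs 1.25)
_PVC_BUMPS = (
    (-0.05, 0.016, -0.20),
    (0.0, 0.024, 1.35),
    (0.06, 0.020, -0.65),
    (0.33, 0.060, 0.35),
)


@dataclass
class SynthSpec:
    """Parameters of one synthetic recording."""

    rhythm: str
    hr_bpm: float = 75.0
    duration_s: float = 8.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rhythm not in RHYTHMS:
            raise EcgKitError(f"unknown rhythm {self.rhythm!r}; choose from {RHYTHMS}")
        if self.duration_s < 8:
            raise EcgKitError("duration must be at least 8 s (one analysis window)")
        if not 30 <= self.hr_bpm <= 220:
            raise EcgKitError("heart rate must lie in [30, 220] bpm")


@dataclass
class SynthTruth:
    """Exact generator-known ground truth."""

    rhythm: str
    r_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    beat_labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _add_bumps(x: np.ndarray, fs: float, t_r: float, bumps) -> None:
    n = x.size
    for dt, width, amp in bumps:
        center = t_r + dt
        lo = max(0, int((center - 4 * width) * fs))
        hi = min(n, int((center + 4 * width) * fs) + 1)
        if lo >= hi:
            continue
        t = np.arange(lo, hi) / fs
        x[lo:hi] += amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def _beat_times(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Scheduled R times from 0.5 s to duration - 0.5 s."""
    times = []
    t = 0.5
    rr_mean = 60.0 / spec.hr_bpm
    while t <= spec.duration_s - 0.5:
        times.append(t)
        if spec.rhythm == "af":
            t += rng.uniform(0.4, 1.2)
        else:
            jitter = np.clip(rng.normal(0.0, 0.01), -0.02, 0.02)
            t += rr_mean * (1.0 + jitter)
    return np.asarray(times)


def _gen_vf(spec: SynthSpec, rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Three drifting 3-7 Hz oscillators with phase noise, waxing-waning
    amplitude envelopes (mean-reverting random walks) and a non-sinusoidal
    waveshape (second and third harmonics), emulating the undulating,
    broadband, non-repeating fibrillatory trajectory that fills a phase
    plot.  Pure tones would trace a thin quasi-periodic curve; the
    harmonics and envelope drift produce the dense, self-crossing cloud
    characteristic of VF."""
    from scipy.signal import lfilter

    x = np.zeros(n)
    for _ in range(3):
        f0 = rng.uniform(3.5, 6.5)
        freq = np.clip(f0 + np.cumsum(rng.normal(0.0, 0.3 / np.sqrt(fs), size=n)), 3.0, 7.0)
        phase = 2 * np.pi * np.cumsum(freq) / fs + np.cumsum(rng.normal(0.0, 0.005, size=n))
        # AR(1) amplitude envelope reverting to 0.8 with per-sample sd 0.03
        e0 = rng.uniform(0.4, 1.2)
        steps = rng.normal(0.0, 0.03, size=n) + 0.02 * 0.8
        env = lfilter([1.0], [1.0, -0.98], steps, zi=[0.98 * e0])[0]
        env = np.clip(env, 0.15, 1.5)
        p0 = rng.uniform(0, 2 * np.pi)
        wave = (np.sin(phase + p0)
                + 0.5 * np.sin(2 * (phase + p0) + rng.uniform(0, 2 * np.pi))
                + 0.25 * np.sin(3 * (phase + p0) + rng.uniform(0, 2 * np.pi)))
        x += env * wave
    return x


def gen_record(spec: SynthSpec) -> tuple[EcgRecord, SynthTruth]:
    """Generate one synthetic recording plus its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    fs = float(TARGET_FS)
    n = int(round(spec.duration_s * fs))
    if spec.rhythm == "vf":
        x = _gen_vf(spec, rng, n, fs)
        truth = SynthTruth(rhythm="vf")
    else:
        times = _beat_times(spec, rng)
        pattern = PATTERNS[spec.rhythm]
        labels = np.array([pattern[i % len(pattern)] for i in range(times.size)], dtype=int)
        x = np.zeros(n)
        for t_r, lab in zip(times, labels):
            _add_bumps(x, fs, t_r, _PVC_BUMPS if lab else _NORMAL_BUMPS)
            if spec.rhythm == "af" and not lab:
                # remove the P bump contribution: AF beats have no P wave
                _add_bumps(x, fs, t_r, ((-0.17, 0.025, -0.15),))
        truth = SynthTruth(
            rhythm=spec.rhythm,
            r_indices=np.round(times * fs).astype(int),
            beat_labels=labels,
        )
    x = x + rng.normal(0.0, spec.noise_sd, size=n)
    record = EcgRecord(samples=x, fs=fs, record_id=f"synth-{spec.rhythm}-{spec.seed}")
    return record, truth


def gen_multirhythm(
    rhythms: list[str],
    seed: int = 0,
    hr_bpm: float = 75.0,
    noise_sd: float = 0.02,
    block_s: float = 8.0,
) -> tuple[EcgRecord, list[SynthTruth]]:
    """Concatenate one 8 s block per requested rhythm into a single record.

    Returns the record plus the per-block ground truth (R indices offset
    into record coordinates).  Analysing the result with non-overlapping
    8 s segmentation aligns each analysis window with exactly one block.
    """
    rng = np.random.default_rng(seed)
    pieces, truths = [], []
    for k, rhythm in enumerate(rhythms):
        spec = SynthSpec(rhythm=rhythm, hr_bpm=hr_bpm, duration_s=block_s,
                         noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)))
        rec, truth = gen_record(spec)
        offset = int(round(k * block_s * TARGET_FS))
        truth.r_indices = truth.r_indices + offset
        pieces.append(rec.samples)
        truths.append(truth)
    record = EcgRecord(samples=np.concatenate(pieces), fs=float(TARGET_FS),
                       record_id=f"synth-multi-{seed}")
    return record, truths


def _gen_segment(spec: SynthSpec):
    """One preprocessed 8 s segment of the given spec, with its truth."""
    record, truth = gen_record(spec)
    seg = preprocess_record(record)[0]
    return seg, truth


_VF_NEGATIVES = ("nsr", "af", "bg", "tg", "qg", "couplet", "triplet", "vt")
_AF_NEGATIVES = ("nsr", "bg", "tg", "qg", "couplet", "triplet")
_PVC_RHYTHMS = ("bg", "tg", "qg", "couplet", "triplet", "vt")


def gen_dataset(stage: str, n_per_class: int, seed: int = 0) -> LabeledDataset:
    """Balanced, feature-extracted dataset for one classification stage.

    Segments (or beats, for the PVC stage) are generated, preprocessed and
    passed through the stage's real feature pipeline; labels are exact by
    construction.  Heart rates are drawn uniformly from [55, 95] bpm.
    """
    if n_per_class < 10:
        raise EcgKitError("need at least 10 samples per class")
    rng = np.random.default_rng(seed)
    if stage == "vf":
        return _gen_segment_dataset(rng, ("vf",), _VF_NEGATIVES, n_per_class,
                                    VfFeatureExtractor())
    if stage == "af":
        return _gen_segment_dataset(rng, ("af",), _AF_NEGATIVES, n_per_class,
                                    AfFeatureExtractor())
    if stage == "pvc":
        return _gen_beat_dataset(rng, n_per_class)
    raise EcgKitError(f"unknown stage {stage!r}; choose vf, af or pvc")


def _spec_stream(rng, rhythms):
    while True:
        for rhythm in rhythms:
            yield SynthSpec(
                rhythm=rhythm,
                hr_bpm=rng.uniform(55.0, 95.0),
                seed=int(rng.integers(0, 2**31 - 1)),
            )


def _gen_segment_dataset(rng, pos_rhythms, neg_rhythms, n_per_class, extractor) -> LabeledDataset:
    rows, labels = [], []
    for rhythms, lab in ((pos_rhythms, 1), (neg_rhythms, 0)):
        stream = _spec_stream(rng, rhythms)
        got = 0
        while got < n_per_class:
            seg, _ = _gen_segment(next(stream))
            row = extractor.fit([seg]).transform([seg])[0]
            if not np.isfinite(row).all():
                continue  # unclassifiable segment (AF stage); draw another
            rows.append(row)
            labels.append(lab)
            got += 1
    return LabeledDataset(np.array(rows), np.array(labels),
                          tuple(extractor.feature_names))


def _gen_beat_dataset(rng, n_per_class) -> LabeledDataset:
    """PVC vs N beats cut at the generator's true R locations."""
    extractor = BeatFeatureExtractor()
    pvc: list[Beat] = []
    normal: list[Beat] = []
    stream = _spec_stream(rng, _PVC_RHYTHMS + ("nsr",))
    while len(pvc) < n_per_class or len(normal) < n_per_class:
        spec = next(stream)
        record, truth = gen_record(spec)
        seg = preprocess_record(record)[0]
        beats = _beats.segment_beats(seg, truth.r_indices)
        kept = [r for r in truth.r_indices if 70 <= r <= len(seg) - 130]
        lab_map = dict(zip(truth.r_indices.tolist(), truth.beat_labels.tolist()))
        for beat, r in zip(beats, kept):
            if lab_map[r] and len(pvc) < n_per_class:
                pvc.append(beat)
            elif not lab_map[r] and len(normal) < n_per_class:
                normal.append(beat)
    all_beats = pvc + normal
    X = extractor.fit(
        np.stack([b.samples for b in all_beats])
    ).transform(np.stack([b.samples for b in all_beats]))
    y = np.array([1] * len(pvc) + [0] * len(normal))
    return LabeledDataset(X, y, tuple(extractor.feature_names))
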