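import numpy as np
import pytest

import ecgkit as ek


def make_segment(rhythm: str, seed: int = 0, hr_bpm: float = 75.0) -> ek.Segment:
    """One preprocessed 8 s segment of a synthetic rhythm."""
    rec, _ = ek.gen_record(ek.SynthSpec(rhythm=rhythm, seed=seed, hr_bpm=hr_bpm))
    return ek.preprocess_record(rec)[0]


def make_record_with_truth(rhythm: str, seed: int = 0, hr_bpm: float = 75.0,
                           duration_s: float = 8.0):
    return ek.gen_record(ek.SynthSpec(rhythm=rhythm, seed=seed, hr_bpm=hr_bpm,
                                      duration_s=duration_s))


@pytest.fixture(scope="session")
def nsr_segment() -> ek.Segment:
    return make_segment("nsr", seed=0)


@pytest.fixture(scope="session")
def vf_segment() -> ek.Segment:
    return make_segment("vf", seed=0)


@pytest.fixture(scope="session")
def stage_datasets():
    """Balanced 200-per-class feature datasets for the three stages."""
    return {stage: ek.gen_dataset(stage, n_per_class=200, seed=11 + i)
            for i, stage in enumerate(("vf", "af", "pvc"))}


@pytest.fixture(scope="session")
def trained_cascade(stage_datasets) -> ek.ArrhythmiaCascade:
    models = [ek.train(stage_datasets[s], kind="bdt", seed=0)
              for s in ("vf", "af", "pvc")]
    return ek.ArrhythmiaCascade(*models)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
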