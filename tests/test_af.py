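"""R-peak detection, RR cleaning, and the AF-stage statistics."""

import numpy as np
import pytest

import ecgkit as ek
from ecgkit.errors import InsufficientBeatsError
from ecgkit.records import RrSeries, Segment
from .conftest import make_record_with_truth


class TestDetectRPeaks:
    @pytest.mark.parametrize("hr,expected", [(60, 8), (100, 13)])
    def test_peak_count_and_timing(self, hr, expected):
        hits = 0
        for seed in range(5):
            rec, truth = make_record_with_truth("nsr", seed=seed, hr_bpm=hr)
            seg = ek.preprocess_record(rec)[0]
            r = ek.detect_r_peaks(seg)
            assert abs(len(r) - expected) <= 1
            # every detection within 25 ms (7.5 samples) of a scheduled beat
            err = np.abs(truth.r_indices[:, None] - r[None, :]).min(axis=0)
            hits += np.all(err <= 7.5)
        assert hits == 5

    def test_flat_segment_yields_nothing(self):
        assert ek.detect_r_peaks(np.zeros(2400), fs=300.0).size == 0

    def test_indices_strictly_increasing(self):
        rec, _ = make_record_with_truth("af", seed=3)
        r = ek.detect_r_peaks(ek.preprocess_record(rec)[0])
        assert np.all(np.diff(r) > 0)


class TestCleanRr:
    def _series(self, rr):
        return RrSeries(rr=np.asarray(rr), r_indices=np.arange(len(rr) + 1))

    def test_physiologic_guard(self):
        out = ek.clean_rr(self._series([0.8, 0.8, 0.05, 0.8, 0.8]))
        np.testing.assert_allclose(out.rr, [0.8, 0.8, 0.8, 0.8])

    def test_all_equal_unchanged(self):
        out = ek.clean_rr(self._series([0.9] * 6))
        np.testing.assert_allclose(out.rr, [0.9] * 6)

    def test_fifty_percent_outlier_removed(self):
        # running median of 5 around the outlier is 0.8 -> 1.2 deviates 50%
        out = ek.clean_rr(self._series([0.8, 0.8, 0.8, 1.2, 0.8, 0.8, 0.8]))
        np.testing.assert_allclose(out.rr, [0.8] * 6)

    def test_too_few_intervals(self):
        with pytest.raises(InsufficientBeatsError):
            ek.clean_rr(self._series([0.8, 0.9]))


class TestRrStatistics:
    def test_rmssd_constant_rr_is_zero(self):
        assert ek.rmssd_norm([1.0, 1.0, 1.0, 1.0]) == 0.0

    def test_rmssd_closed_form(self):
        assert ek.rmssd_norm([0.8, 1.2]) == pytest.approx(0.4)

    def test_rmssd_matches_loop_oracle(self, rng):
        for _ in range(200):
            rr = rng.uniform(0.4, 1.2, size=rng.integers(2, 50))
            diffs = [rr[i + 1] - rr[i] for i in range(len(rr) - 1)]
            expected = np.sqrt(sum(d * d for d in diffs) / len(diffs)) / np.mean(rr)
            assert ek.rmssd_norm(rr) == pytest.approx(expected, abs=1e-9)

    def test_tpr_monotone_is_zero(self):
        assert ek.turning_point_ratio(np.linspace(0.5, 1.5, 20)) == 0.0

    def test_tpr_alternating_is_one(self):
        assert ek.turning_point_ratio([0.8, 1.2] * 10) == 1.0

    def test_tpr_ties_are_not_turning_points(self):
        assert ek.turning_point_ratio([1.0, 1.0, 1.0, 1.0]) == 0.0

    def test_tpr_random_sequence_expectation(self, rng):
        # expected fraction of interior turning points in an iid sequence is 2/3
        vals = [ek.turning_point_ratio(rng.random(200)) for _ in range(1000)]
        assert np.mean(vals) == pytest.approx(2 / 3, abs=0.02)

    def test_tpr_matches_loop_oracle(self, rng):
        for _ in range(200):
            rr = rng.uniform(0.4, 1.2, size=rng.integers(3, 60))
            t = sum(1 for i in range(1, len(rr) - 1)
                    if (rr[i] > rr[i - 1] and rr[i] > rr[i + 1])
                    or (rr[i] < rr[i - 1] and rr[i] < rr[i + 1]))
            assert ek.turning_point_ratio(rr) == pytest.approx(t / (len(rr) - 2))

    def test_rr_entropy_limits(self):
        assert ek.rr_shannon_entropy(np.full(20, 0.8)) == 0.0
        spread = np.linspace(0.4, 1.2, 16) + 1e-4
        assert ek.rr_shannon_entropy(spread) == pytest.approx(1.0, abs=1e-9)

    def test_rr_entropy_guard(self):
        with pytest.raises(InsufficientBeatsError):
            ek.rr_shannon_entropy(np.array([0.8, 0.9, 1.0]), n_bins=16)


class TestAfFeatures:
    def test_nsr_has_low_normalized_rmssd(self):
        for seed in range(10):
            rec, _ = make_record_with_truth("nsr", seed=seed)
            fv = ek.af_features(ek.preprocess_record(rec)[0])
            assert fv.ok
            assert fv.rmssd_n < 0.1

    def test_af_is_irregular(self):
        # the ectopic-interval exclusion clips some genuine AF variability
        # in a short 8 s window, so a single seed can fall below 0.2 while
        # remaining far above the NSR level (< 0.1)
        high = 0
        for seed in range(10):
            rec, _ = make_record_with_truth("af", seed=seed)
            fv = ek.af_features(ek.preprocess_record(rec)[0])
            assert fv.ok
            assert fv.rmssd_n > 0.1
            high += fv.rmssd_n > 0.2
            # with ~9 intervals TPR is quantised in steps of 1/7; iid RR
            # centres it near 2/3
            assert 0.4 <= fv.tpr <= 1.0
        assert high >= 9

    def test_too_few_beats_flagged_not_dropped(self):
        # a near-flat segment with a couple of bumps cannot be classified
        x = np.zeros(2400)
        x[1000] = 1.0
        x[1400] = 1.0
        seg = Segment(samples=ek.normalize(x), fs=300.0)
        fv = ek.af_features(seg)
        assert not fv.ok
        assert np.isnan(fv.rmssd_n)

    def test_features_blind_to_amplitude(self):
        rec, _ = make_record_with_truth("af", seed=5)
        seg = ek.preprocess_record(rec)[0]
        fv1 = ek.af_features(seg)
        # RR statistics operate on detected intervals only
        fv2 = ek.af_features(Segment(samples=seg.samples.copy(), fs=300.0))
        assert fv1.as_array() == pytest.approx(fv2.as_array())
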