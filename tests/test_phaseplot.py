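"""Phase-plot image construction and the four VF image features.

The diagonal-line detector, image subtraction and hole filling are each
checked exactly against independent brute-force oracles on random masks.
"""

import numpy as np
import pytest

import ecgkit as ek
from ecgkit.errors import EcgKitError
from ecgkit.phaseplot import PhasePlotImage
from .conftest import make_segment


# ---------------------------------------------------------------------------
# brute-force oracles

def oracle_diagonal_lines(grid: np.ndarray, min_len: int = 20):
    """Enumerate every (+1,+1) diagonal, scan runs of 1s with a plain loop."""
    n = grid.shape[0]
    count, covered = 0, 0
    for offset in range(-(n - 1), n):
        cells = [grid[i, i + offset] for i in range(n) if 0 <= i + offset < n]
        run = 0
        for v in cells + [0]:
            if v:
                run += 1
            else:
                if run > min_len:
                    count += 1
                    covered += run
                run = 0
    return count, covered


def oracle_fill(grid: np.ndarray) -> int:
    """Flood-fill the 4-connected background from the border; holes become 1s."""
    n, m = grid.shape
    outside = np.zeros_like(grid, dtype=bool)
    stack = [(i, j) for i in range(n) for j in (0, m - 1) if not grid[i, j]]
    stack += [(i, j) for i in (0, n - 1) for j in range(m) if not grid[i, j]]
    while stack:
        i, j = stack.pop()
        if outside[i, j] or grid[i, j]:
            continue
        outside[i, j] = True
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if 0 <= a < n and 0 <= b < m and not outside[a, b] and not grid[a, b]:
                stack.append((a, b))
    return int(np.sum(grid == 1) + np.sum((grid == 0) & ~outside))


def _img(grid):
    return PhasePlotImage(grid=np.asarray(grid, dtype=np.uint8), lag=1)


# ---------------------------------------------------------------------------

class TestBuildPhasePlot:
    def test_linear_ramp_stays_on_main_diagonal(self):
        x = np.linspace(-2.9, 2.9, 2400)
        img = ek.build_phase_plot(x, lag=1, resolution=100)
        ii, jj = np.nonzero(img.grid)
        assert np.all(np.abs(ii - jj) <= 1)  # chords hug y = x

    def test_embedding_point_count(self):
        x = np.random.default_rng(0).normal(size=2400)
        assert ek.embed(x, lag=5).shape == (2395, 2)

    def test_lag_must_be_smaller_than_segment(self):
        with pytest.raises(EcgKitError):
            ek.build_phase_plot(np.zeros(10), lag=10)

    def test_noise_occupies_more_cells_than_tone(self):
        t = np.arange(2400) / 300.0
        tone = ek.normalize(np.sin(2 * np.pi * 1.0 * t))
        for seed in range(10):
            noise = np.random.default_rng(seed).normal(size=2400)
            n_noise = ek.build_phase_plot(noise, lag=5).n_white
            n_tone = ek.build_phase_plot(tone, lag=5).n_white
            assert n_noise > n_tone

    def test_point_mode_marks_at_most_one_cell_per_point(self):
        x = np.random.default_rng(2).normal(size=500)
        img = ek.build_phase_plot(x, lag=5, connect=False)
        assert img.n_white <= 495


class TestSelfSimilarity:
    def test_identical_images_give_zero(self):
        ones = _img(np.ones((50, 50)))
        assert ek.f1_self_similarity(ones, ones) == 0.0

    def test_empty_vs_full(self):
        assert ek.f1_self_similarity(_img(np.zeros((50, 50))), _img(np.ones((50, 50)))) == 1.0

    def test_matches_pixel_count_oracle(self, rng):
        for _ in range(20):
            g1 = (rng.random((100, 100)) < 0.3).astype(np.uint8)
            g2 = (rng.random((100, 100)) < 0.3).astype(np.uint8)
            expected = (int(g2.sum()) - int(g1.sum())) / 10000
            assert ek.f1_self_similarity(_img(g1), _img(g2)) == pytest.approx(expected)

    def test_resolution_mismatch_rejected(self):
        with pytest.raises(EcgKitError):
            ek.f1_self_similarity(_img(np.zeros((50, 50))), _img(np.zeros((60, 60))))


class TestDiagonalLines:
    def test_single_run_of_25(self):
        g = np.zeros((100, 100), dtype=np.uint8)
        for k in range(25):
            g[10 + k, 30 + k] = 1
        assert ek.detect_diagonal_lines(_img(g)) == (1, 25)

    def test_run_of_exactly_20_not_counted(self):
        g = np.zeros((100, 100), dtype=np.uint8)
        for k in range(20):
            g[k, k] = 1
        assert ek.detect_diagonal_lines(_img(g)) == (0, 0)

    def test_matches_oracle_on_random_masks(self, rng):
        for _ in range(200):
            g = (rng.random((100, 100)) < rng.uniform(0.3, 0.9)).astype(np.uint8)
            assert ek.detect_diagonal_lines(_img(g)) == oracle_diagonal_lines(g)


class TestSubtract:
    def test_self_subtraction_empty(self, rng):
        g = (rng.random((40, 40)) < 0.5).astype(np.uint8)
        assert ek.subtract_images(_img(g), _img(g)).n_white == 0

    def test_subtracting_empty_is_identity(self, rng):
        g = (rng.random((40, 40)) < 0.5).astype(np.uint8)
        out = ek.subtract_images(_img(g), _img(np.zeros((40, 40))))
        np.testing.assert_array_equal(out.grid, g)

    def test_matches_clamped_oracle(self, rng):
        for _ in range(50):
            g1 = (rng.random((60, 60)) < 0.4).astype(np.uint8)
            g2 = (rng.random((60, 60)) < 0.4).astype(np.uint8)
            expected = np.maximum(g1.astype(int) - g2.astype(int), 0)
            np.testing.assert_array_equal(
                ek.subtract_images(_img(g1), _img(g2)).grid, expected)


class TestFill:
    def test_empty_image(self):
        assert ek.f4_fill_count(_img(np.zeros((10, 10)))) == 0.0

    def test_ring_fills_interior(self):
        g = np.zeros((10, 10), dtype=np.uint8)
        g[3:6, 3:6] = 1
        g[4, 4] = 0  # 3x3 ring with a hole in the middle
        assert ek.f4_fill_count(_img(g)) == pytest.approx(9 / 100)

    def test_fill_only_adds_pixels(self, rng):
        for _ in range(20):
            g = (rng.random((50, 50)) < 0.4).astype(np.uint8)
            assert ek.f4_fill_count(_img(g)) >= g.sum() / g.size

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(200):
            g = (rng.random((30, 30)) < rng.uniform(0.2, 0.6)).astype(np.uint8)
            assert ek.f4_fill_count(_img(g)) == pytest.approx(oracle_fill(g) / g.size)


class TestVfImageFeatures:
    def test_sign_flip_invariance(self, nsr_segment):
        a = ek.vf_image_features(nsr_segment.samples)
        b = ek.vf_image_features(-nsr_segment.samples)
        assert (a.f1, a.f2, a.f3, a.f4) == pytest.approx((b.f1, b.f2, b.f3, b.f4))

    def test_pure_sinusoid_traces_thin_curve(self):
        t = np.arange(2400) / 300.0
        tone = ek.normalize(np.sin(2 * np.pi * 2.0 * t))
        feats = ek.vf_image_features(tone)
        assert feats.f4 < 0.05

    def test_f3_at_least_min_len_times_f2(self, vf_segment):
        feats = ek.vf_image_features(vf_segment.samples)
        assert feats.f2 > 0
        assert feats.f3 >= 20 * feats.f2

    def test_vf_more_lines_and_fill_than_nsr(self):
        wins = 0
        for seed in range(10):
            fv = ek.vf_image_features(make_segment("vf", seed).samples)
            fn = ek.vf_image_features(make_segment("nsr", seed).samples)
            wins += fv.f2 > fn.f2 and fv.f4 > fn.f4
        assert wins >= 9
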