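import numpy as np
import pytest

from aggrgan.aggregation import (CandidateSet, EdgeMap, WeightMap, aggregate,
                                 assign_weights, blend, gaussian_edge_value,
                                 gaussian_kernel1d, select_top_two,
                                 sobel_edge_map)
from aggrgan.imaging import GrayImage
from aggrgan.metrics import compute_ssim
from _oracles import aggregate_oracle, gaussian_oracle, sobel_oracle


def u8(arr):
    return GrayImage(np.asarray(arr, dtype=np.uint8), "uint8")


class TestSobel:
    def test_constant_image_has_no_edges(self):
        em = sobel_edge_map(u8(np.full((6, 6), 77)))
        assert np.all(em.magnitudes == 0)

    def test_vertical_step_peaks_at_the_step(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[:, 4:] = 255
        em = sobel_edge_map(u8(img)).magnitudes
        # maxima in the two columns adjacent to the step, zero far away
        assert em[:, 3:5].min() > 0
        assert np.all(em[:, 0:2] == 0) and np.all(em[:, 6:] == 0)
        assert em.max() == em[4, 4]

    def test_matches_hand_convolution(self, rng):
        img = rng.integers(0, 256, (4, 4), dtype=np.uint8)
        got = sobel_edge_map(u8(img)).magnitudes
        np.testing.assert_allclose(got, sobel_oracle(img.astype(float)),
                                   atol=1e-10)


class TestGaussianEdgeValue:
    def test_zero_map_stays_zero(self):
        out = gaussian_edge_value(EdgeMap(np.zeros((5, 5))), 1.0)
        assert np.all(out.magnitudes == 0)

    def test_impulse_center_equals_kernel_center_weight(self):
        k = gaussian_kernel1d(1.0)
        imp = np.zeros((9, 9))
        imp[4, 4] = 1.0
        out = gaussian_edge_value(EdgeMap(imp), 1.0)
        assert out.magnitudes[4, 4] == pytest.approx(k[len(k) // 2] ** 2, rel=1e-12)

    def test_semigroup_within_truncation_error(self):
        # double smoothing at sigma vs single pass at sigma*sqrt(2); the
        # radius-3*sigma kernel truncation bounds the achievable agreement
        imp = np.zeros((21, 21))
        imp[10, 10] = 1.0
        twice = gaussian_edge_value(gaussian_edge_value(EdgeMap(imp), 1.0), 1.0)
        once = gaussian_edge_value(EdgeMap(imp), np.sqrt(2.0))
        assert np.abs(twice.magnitudes - once.magnitudes).max() < 5e-4

    def test_mean_preserved_on_interior_dominated_map(self, rng):
        a = np.abs(rng.standard_normal((64, 64))) + 1.0
        out = gaussian_edge_value(EdgeMap(a), 1.0)
        assert out.magnitudes.mean() == pytest.approx(a.mean(), rel=0.01)

    def test_matches_hand_two_pass(self, rng):
        a = np.abs(rng.standard_normal((6, 6))) * 10
        got = gaussian_edge_value(EdgeMap(a), 1.0).magnitudes
        np.testing.assert_allclose(got, gaussian_oracle(a, 1.0), atol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_edge_value(EdgeMap(np.zeros((4, 4))), 0.0)


def _cands(scores, imgs=None):
    if imgs is None:
        base = np.zeros((4, 4), dtype=np.uint8)
        imgs = (u8(base), u8(base + 1), u8(base + 2))
    return CandidateSet(images=imgs, scores=tuple(scores), metric_name="ssim")


class TestSelectTopTwo:
    @pytest.mark.parametrize("scores,expected", [
        ((0.40, 0.68, 0.62), (1, 2)),   # weakest candidate dropped
        ((0.5, 0.5, 0.1), (0, 1)),       # tie broken toward lower index
        ((0.3, 0.3, 0.3), (0, 1)),       # full tie
        ((0.1, 0.2, np.inf), (2, 1)),    # sentinel sorts above finite scores
    ])
    def test_selection(self, scores, expected):
        assert select_top_two(_cands(scores)) == expected


class TestAssignWeights:
    def test_equal_edges_equal_scores_split_evenly(self):
        g = EdgeMap(np.full((4, 4), 3.0))
        w = assign_weights(g, g, 0.5, 0.5)
        np.testing.assert_allclose(w.w1, 0.5)
        np.testing.assert_allclose(w.w2, 0.5)

    def test_edgeless_competitor_loses_everywhere_edges_exist(self):
        g1 = EdgeMap(np.full((4, 4), 2.0))
        g2 = EdgeMap(np.zeros((4, 4)))
        w = assign_weights(g1, g2, 0.5, 0.5)
        np.testing.assert_allclose(w.w1, 1.0)

    def test_scalar_example(self):
        w = assign_weights(EdgeMap(np.full((2, 2), 2.0)),
                           EdgeMap(np.full((2, 2), 1.0)), 0.6, 0.4)
        np.testing.assert_allclose(w.w1, 1.2 / 1.6)

    def test_zero_edge_pixels_fall_back_to_metric_split(self):
        g0 = EdgeMap(np.zeros((3, 3)))
        w = assign_weights(g0, g0, 0.75, 0.25)
        np.testing.assert_allclose(w.w1, 0.75)

    def test_weights_sum_to_one_everywhere(self, rng):
        for _ in range(10):
            g1 = EdgeMap(np.abs(rng.standard_normal((5, 5))))
            g2 = EdgeMap(np.abs(rng.standard_normal((5, 5))))
            m1, m2 = rng.uniform(0, 1, 2)
            w = assign_weights(g1, g2, m1, m2 + 1e-6)
            np.testing.assert_allclose(w.w1 + w.w2, 1.0, atol=1e-12)

    def test_both_scores_zero_rejected(self):
        g = EdgeMap(np.ones((3, 3)))
        with pytest.raises(ValueError):
            assign_weights(g, g, 0.0, 0.0)


class TestBlend:
    def test_identical_inputs_idempotent(self, rng):
        img = u8(rng.integers(0, 256, (5, 5)))
        w1 = rng.uniform(0, 1, (5, 5))
        out = blend(img, img, WeightMap(w1, 1 - w1))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_unit_weight_selects_first_bit_exact(self, rng):
        a = u8(rng.integers(0, 256, (5, 5)))
        b = u8(rng.integers(0, 256, (5, 5)))
        out = blend(a, b, WeightMap(np.ones((5, 5)), np.zeros((5, 5))))
        np.testing.assert_array_equal(out.pixels, a.pixels)

    def test_half_weight_checkerboard(self):
        a = u8([[0, 255], [255, 0]])
        b = u8([[255, 0], [0, 255]])
        half = np.full((2, 2), 0.5)
        out = blend(a, b, WeightMap(half, half))
        # 127.5 rounds half-to-even -> 128
        np.testing.assert_array_equal(out.pixels, np.full((2, 2), 128))

    def test_convexity_bounds(self, rng):
        a = u8(rng.integers(0, 256, (6, 6)))
        b = u8(rng.integers(0, 256, (6, 6)))
        w1 = rng.uniform(0, 1, (6, 6))
        out = blend(a, b, WeightMap(w1, 1 - w1)).pixels.astype(int)
        lo = np.minimum(a.pixels, b.pixels).astype(int)
        hi = np.maximum(a.pixels, b.pixels).astype(int)
        assert np.all(out >= lo) and np.all(out <= hi)

    def test_invalid_weight_map_rejected(self):
        with pytest.raises(ValueError):
            WeightMap(np.full((2, 2), 0.7), np.full((2, 2), 0.7))


class TestAggregate:
    def test_three_identical_candidates_return_identity(self, rng):
        img = u8(rng.integers(0, 256, (8, 8)))
        cands = CandidateSet(images=(img, img, img), scores=(0.5, 0.5, 0.5))
        out = aggregate(cands)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_reference_copy_is_always_selected(self, phantom64, rng):
        # a candidate equal to the reference scores SSIM exactly 1: maximal
        noisy1 = u8(np.clip(phantom64.astype_float()
                            + rng.normal(0, 30, (64, 64)), 0, 255))
        noisy2 = u8(np.clip(phantom64.astype_float()
                            + rng.normal(0, 50, (64, 64)), 0, 255))
        imgs = (noisy1, phantom64, noisy2)
        scores = tuple(compute_ssim(im, phantom64) for im in imgs)
        assert scores[1] == 1.0
        i, j = select_top_two(CandidateSet(images=imgs, scores=scores))
        assert i == 1

    def test_deterministic(self, rng):
        imgs = tuple(u8(rng.integers(0, 256, (8, 8))) for _ in range(3))
        cands = CandidateSet(images=imgs, scores=(0.2, 0.9, 0.5))
        a = aggregate(cands, sigma=1.0)
        b = aggregate(cands, sigma=1.0)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_permutation_consistency(self, rng):
        imgs = [u8(rng.integers(0, 256, (8, 8))) for _ in range(3)]
        scores = [0.9, 0.6, 0.1]
        out = aggregate(CandidateSet(images=tuple(imgs), scores=tuple(scores)))
        # swap the two selected candidates (positions 0 and 1)
        imgs2 = (imgs[1], imgs[0], imgs[2])
        scores2 = (scores[1], scores[0], scores[2])
        out2 = aggregate(CandidateSet(images=imgs2, scores=scores2))
        np.testing.assert_array_equal(out.pixels, out2.pixels)

    def test_agrees_with_naive_reference_bit_exact(self):
        g = np.random.default_rng(7)
        for _ in range(5):
            imgs = [g.integers(0, 256, (8, 8)).astype(np.uint8) for _ in range(3)]
            scores = tuple(float(s) for s in g.uniform(0.1, 1.0, 3))
            cands = CandidateSet(images=tuple(u8(a) for a in imgs), scores=scores)
            got = aggregate(cands, sigma=1.0)
            exp = aggregate_oracle(imgs, scores, 1.0)
            np.testing.assert_array_equal(got.pixels, exp)

    def test_psnr_sentinel_scores_are_rank_transformed(self, rng):
        a = u8(rng.integers(0, 256, (6, 6)))
        b = u8(rng.integers(0, 256, (6, 6)))
        cands = CandidateSet(images=(a, a, b), scores=(np.inf, 20.0, 10.0),
                             metric_name="psnr")
        out = aggregate(cands)  # must not produce nan/crash
        assert out.pixels.dtype == np.uint8

    def test_candidate_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            CandidateSet(images=(u8(np.zeros((4, 4))), u8(np.zeros((4, 5))),
                                 u8(np.zeros((4, 4)))), scores=(0.1, 0.2, 0.3))
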