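import math

import numpy as np
import pytest

from aggrgan.imaging import GrayImage
from aggrgan.metrics import (C1_DEFAULT, C2_DEFAULT, Histogram, MetricReport,
                             compute_kl, compute_psnr, compute_sd, compute_ssim,
                             evaluate, image_histogram)
from _oracles import (histogram_oracle, kl_oracle, psnr_oracle, sd_oracle,
                      ssim_oracle)


def u8(arr):
    return GrayImage(np.asarray(arr, dtype=np.uint8), "uint8")


class TestSSIM:
    def test_identity_is_exactly_one(self, rng):
        for _ in range(20):
            img = u8(rng.integers(0, 256, (9, 7)))
            assert compute_ssim(img, img) == 1.0

    def test_identical_constants(self):
        z = u8(np.zeros((4, 4)))
        assert compute_ssim(z, z) == 1.0

    def test_two_by_two_hand_case(self):
        # x = [[0,255],[255,0]], y = [[0,0],[255,255]]: means 127.5 each,
        # variances 127.5^2, covariance 0 (independent scalar arithmetic)
        x = u8([[0, 255], [255, 0]])
        y = u8([[0, 0], [255, 255]])
        mu = 127.5
        expected = ((2 * mu * mu + C1_DEFAULT) * (0.0 + C2_DEFAULT)
                    / ((2 * mu * mu + C1_DEFAULT) * (2 * mu * mu + C2_DEFAULT)))
        assert compute_ssim(x, y) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(10):
            a = u8(rng.integers(0, 256, (6, 6)))
            b = u8(rng.integers(0, 256, (6, 6)))
            assert compute_ssim(a, b) == pytest.approx(compute_ssim(b, a), abs=1e-14)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_ssim(u8(np.zeros((4, 4))), u8(np.zeros((4, 5))))

    def test_nonpositive_constants_rejected(self):
        z = u8(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            compute_ssim(z, z, c1=0.0)

    def test_matches_single_window_toolkit_ssim(self, rng):
        skimage = pytest.importorskip("skimage.metrics")
        a = rng.integers(0, 256, (7, 7), dtype=np.uint8)
        b = rng.integers(0, 256, (7, 7), dtype=np.uint8)
        ref = skimage.structural_similarity(
            a, b, win_size=7, data_range=255, gaussian_weights=False,
            use_sample_covariance=False)
        assert compute_ssim(u8(a), u8(b)) == pytest.approx(ref, abs=1e-9)


class TestPSNR:
    def test_identity_is_infinite(self, rng):
        img = u8(rng.integers(0, 256, (5, 5)))
        assert compute_psnr(img, img) == math.inf

    def test_full_swing_is_zero_db(self):
        assert compute_psnr(u8(np.zeros((4, 4))),
                            u8(np.full((4, 4), 255))) == pytest.approx(0.0)

    def test_unit_offset_closed_form(self, rng):
        x = rng.integers(0, 255, (6, 6)).astype(np.uint8)  # headroom for +1
        assert compute_psnr(u8(x), u8(x + 1)) == pytest.approx(
            20 * math.log10(255.0), abs=1e-12)

    def test_decreases_with_noise_variance(self, phantom64):
        g = np.random.default_rng(5)
        f = phantom64.astype_float()
        vals = []
        for sd in (5, 20, 60):
            noisy = u8(np.clip(f + g.normal(0, sd, f.shape), 0, 255))
            vals.append(compute_psnr(phantom64, noisy))
        assert vals[0] > vals[1] > vals[2]

    def test_toolkit_cross_check(self, rng):
        skimage = pytest.importorskip("skimage.metrics")
        a = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        b = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        assert compute_psnr(u8(a), u8(b)) == pytest.approx(
            skimage.peak_signal_noise_ratio(a, b, data_range=255), abs=1e-9)


class TestHistogramKL:
    def test_delta_histogram(self):
        h = image_histogram(u8(np.zeros((2, 2))))
        assert h.probs[0] == 1.0 and h.probs[1:].sum() == 0.0

    def test_two_level_counts(self):
        h = image_histogram(u8([[0, 255], [0, 255]]))
        assert h.probs[0] == 0.5 and h.probs[255] == 0.5

    def test_probabilities_normalized(self, rng):
        h = image_histogram(u8(rng.integers(0, 256, (16, 16))))
        assert h.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_kl_self_is_zero(self, rng):
        h = image_histogram(u8(rng.integers(0, 256, (8, 8))))
        assert compute_kl(h, h) == pytest.approx(0.0, abs=1e-9)

    def test_kl_two_point_vs_point_mass(self):
        p = np.zeros(256)
        p[0] = p[255] = 0.5
        q = np.zeros(256)
        q[0] = 1.0
        eps = 1e-10
        got = compute_kl(Histogram(p), Histogram(q), eps=eps)
        expected = kl_oracle(p, q, eps)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 10  # strongly divergent pair
        # asymmetry of the divergence
        assert compute_kl(Histogram(q), Histogram(p), eps=eps) != pytest.approx(got)

    def test_kl_nonnegative_on_random_pairs(self):
        g = np.random.default_rng(11)
        for _ in range(1000):
            p = g.dirichlet(np.full(256, 0.05))
            q = g.dirichlet(np.full(256, 0.05))
            assert compute_kl(Histogram(p), Histogram(q)) >= 0.0

    def test_invalid_histogram_rejected(self):
        with pytest.raises(ValueError):
            Histogram(np.full(256, 1.0))
        with pytest.raises(ValueError):
            compute_kl(Histogram(np.full(256, 1 / 256)),
                       Histogram(np.full(256, 1 / 256)), eps=0.0)


class TestSharpnessDifference:
    def test_identity_is_infinite(self, rng):
        img = u8(rng.integers(0, 256, (5, 5)))
        assert compute_sd(img, img) == math.inf

    def test_distinct_constants_are_infinite(self):
        assert compute_sd(u8(np.zeros((4, 4))),
                          u8(np.full((4, 4), 100))) == math.inf

    def test_three_by_three_hand_pair(self):
        x = u8([[10, 20, 30], [40, 50, 60], [70, 80, 90]])
        y = u8([[90, 10, 40], [20, 200, 5], [60, 30, 250]])
        assert compute_sd(x, y) == pytest.approx(
            sd_oracle(x.pixels, y.pixels), abs=1e-12)


class TestEvaluate:
    def test_identity_bundle(self, phantom64):
        rep = evaluate(phantom64, phantom64)
        assert rep.ssim == 1.0 and rep.kl == pytest.approx(0.0, abs=1e-9)
        assert rep.psnr == math.inf and rep.sd == math.inf

    def test_noisy_pair_all_finite(self, phantom64):
        g = np.random.default_rng(3)
        noisy = u8(np.clip(phantom64.astype_float() + g.normal(0, 15, (64, 64)),
                           0, 255))
        rep = evaluate(noisy, phantom64)
        assert 0 < rep.ssim < 1
        assert math.isfinite(rep.psnr) and math.isfinite(rep.sd)
        assert rep.kl > 0

    def test_composition_equals_standalone_metrics(self, rng):
        a = u8(rng.integers(0, 256, (8, 8)))
        b = u8(rng.integers(0, 256, (8, 8)))
        rep = evaluate(a, b)
        assert rep.ssim == compute_ssim(a, b)
        assert rep.psnr == compute_psnr(a, b)
        assert rep.kl == compute_kl(image_histogram(a), image_histogram(b))
        assert rep.sd == compute_sd(a, b)

    def test_report_invariants_enforced(self):
        with pytest.raises(ValueError):
            MetricReport(ssim=1.5, psnr=1.0, kl=0.0, sd=1.0)
        with pytest.raises(ValueError):
            MetricReport(ssim=0.5, psnr=1.0, kl=-0.1, sd=1.0)


@pytest.mark.parametrize("metric,oracle", [
    ("ssim", lambda a, b: ssim_oracle(a, b, C1_DEFAULT, C2_DEFAULT)),
    ("psnr", psnr_oracle),
    ("kl", None),
    ("sd", sd_oracle),
])
def test_brute_force_oracle_equivalence(metric, oracle):
    """Each metric agrees with an independently coded double-loop
    implementation on random small images (tolerance 1e-9)."""
    g = np.random.default_rng(99)
    for _ in range(50):
        m = int(g.integers(2, 9))
        n = int(g.integers(2, 9))
        a = g.integers(0, 256, (m, n)).astype(np.uint8)
        b = g.integers(0, 256, (m, n)).astype(np.uint8)
        ia, ib = u8(a), u8(b)
        if metric == "ssim":
            assert compute_ssim(ia, ib) == pytest.approx(oracle(a, b), abs=1e-9)
        elif metric == "psnr":
            got, exp = compute_psnr(ia, ib), oracle(a, b)
            assert (got == exp == math.inf) or got == pytest.approx(exp, abs=1e-9)
        elif metric == "kl":
            got = compute_kl(image_histogram(ia), image_histogram(ib))
            exp = kl_oracle(histogram_oracle(a), histogram_oracle(b), 1e-10)
            assert got == pytest.approx(exp, abs=1e-9)
        else:
            got, exp = compute_sd(ia, ib), oracle(a, b)
            assert (got == exp == math.inf) or got == pytest.approx(exp, abs=1e-9)
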