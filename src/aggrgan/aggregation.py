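"""Edge-priority aggregation of GAN outputs.

Given three candidate images and a raw reference, the two candidates scoring
highest on a reference metric (SSIM or PSNR) are fused pixel by pixel.  The
blend weight of each candidate at a pixel is proportional to the product of
its Gaussian-smoothed Sobel edge magnitude there and its image-level metric
score, so strong edges of the better-scoring candidate dominate the fused
image.

The weight rule w1 = g1*m1 / (g1*m1 + g2*m2) is this package's own
formalization of "edge priority scaled by metric score": both the per-pixel
smoothed edge value and the image-level metric must drive the weights, and
this is the simplest rule that reduces correctly in every degenerate limit
(equal edges and scores -> 0.5; one candidate edgeless -> the other wins;
both edgeless at a pixel -> weights proportional to the metric scores).
See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import GrayImage

SIGMA_DEFAULT = 1.0


@dataclass(frozen=True)
class EdgeMap:
    """Per-pixel nonnegative edge magnitudes."""

    magnitudes: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.magnitudes, dtype=np.float64)
        if m.ndim != 2:
            raise ValueError("EdgeMap must be 2-D")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("edge magnitudes must be finite and nonnegative")
        object.__setattr__(self, "magnitudes", m)


@dataclass(frozen=True)
class WeightMap:
    """Two per-pixel blend weights that sum to one everywhere."""

    w1: np.ndarray
    w2: np.ndarray

    def __post_init__(self):
        w1 = np.asarray(self.w1, dtype=np.float64)
        w2 = np.asarray(self.w2, dtype=np.float64)
        if w1.shape != w2.shape:
            raise ValueError("weight grids must share a shape")
        for w in (w1, w2):
            if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
                raise ValueError("weights must lie in [0, 1]")
        if np.max(np.abs(w1 + w2 - 1.0)) > 1e-9:
            raise ValueError("weights must sum to 1 at every pixel")
        object.__setattr__(self, "w1", w1)
        object.__setattr__(self, "w2", w2)


@dataclass(frozen=True)
class CandidateSet:
    """Three candidate images with their metric scores against a reference."""

    images: tuple[GrayImage, GrayImage, GrayImage]
    scores: tuple[float, float, float]
    metric_name: str = "ssim"

    def __post_init__(self):
        if len(self.images) != 3 or len(self.scores) != 3:
            raise ValueError("a CandidateSet holds exactly 3 images and 3 scores")
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError(f"candidate shapes differ: {shapes}")
        if self.metric_name.lower() not in ("ssim", "psnr"):
            raise ValueError("metric_name must be 'ssim' or 'psnr'")
        for s in self.scores:
            if math.isnan(s):
                raise ValueError("candidate scores must be finite or +inf")


def sobel_edge_map(img: GrayImage) -> EdgeMap:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) from the standard 3x3 Sobel
    kernels, reflect border handling."""
    f = img.astype_float()
    gr = ndimage.sobel(f, axis=0, mode="reflect")
    gc = ndimage.sobel(f, axis=1, mode="reflect")
    return EdgeMap(np.sqrt(gr * gr + gc * gc))


def gaussian_kernel1d(sigma: float) -> np.ndarray:
    """Normalized 1-D Gaussian, truncated at radius round(3*sigma) (>= 1)."""
    r = max(1, int(round(3.0 * sigma)))
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x * x) / (2.0 * sigma * sigma))
    return k / k.sum()


def gaussian_edge_value(edges: EdgeMap, sigma: float = SIGMA_DEFAULT) -> EdgeMap:
    """Gaussian smoothing of the edge-magnitude grid (separable two-pass
    convolution, reflect borders): spreads edge priority to a neighborhood."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    k = gaussian_kernel1d(sigma)
    sm = ndimage.correlate1d(edges.magnitudes, k, axis=0, mode="reflect")
    sm = ndimage.correlate1d(sm, k, axis=1, mode="reflect")
    return EdgeMap(np.maximum(sm, 0.0))


def select_top_two(cands: CandidateSet) -> tuple[int, int]:
    """Indices of the two best-scoring candidates, best first; ties broken
    toward the lower index."""
    order = sorted(range(3), key=lambda i: (-cands.scores[i], i))
    return order[0], order[1]


def assign_weights(g1: EdgeMap, g2: EdgeMap, m1: float, m2: float) -> WeightMap:
    """Per-pixel weights w1 = g1*m1 / (g1*m1 + g2*m2); where both weighted
    edge values vanish, fall back to the metric-proportional split."""
    if g1.magnitudes.shape != g2.magnitudes.shape:
        raise ValueError("edge maps must share a shape")
    if m1 < 0 or m2 < 0:
        raise ValueError("metric scores must be nonnegative")
    if m1 == 0 and m2 == 0:
        raise ValueError("at least one metric score must be positive")
    a = g1.magnitudes * m1
    b = g2.magnitudes * m2
    den = a + b
    fallback = m1 / (m1 + m2)
    with np.errstate(invalid="ignore"):
        w1 = np.where(den > 0, np.divide(a, den, out=np.full_like(a, fallback),
                                         where=den > 0), fallback)
    return WeightMap(w1, 1.0 - w1)


def blend(img1: GrayImage, img2: GrayImage, w: WeightMap) -> GrayImage:
    """Pixel-wise convex combination, rounded half-to-even back to uint8.
    Every output pixel lies within [min, max] of the two input pixels."""
    if img1.shape != img2.shape or img1.shape != w.w1.shape:
        raise ValueError("image and weight shapes must match")
    f1, f2 = img1.astype_float(), img2.astype_float()
    out = np.rint(w.w1 * f1 + w.w2 * f2).astype(np.uint8)
    return GrayImage(out, "uint8")


def _effective_scores(cands: CandidateSet, i: int, j: int) -> tuple[float, float]:
    """Map raw scores of the selected pair onto nonnegative finite weights.

    PSNR can be the +inf sentinel (identical images) and SSIM can be
    negative; infinite scores are rank-transformed (2 for the better, 1 for
    the other; 1,1 on an all-infinite tie) and negative SSIM clamps to 0
    (with an equal-split fallback if both clamp)."""
    m1, m2 = cands.scores[i], cands.scores[j]
    if math.isinf(m1) or math.isinf(m2):
        if m1 == m2:
            return 1.0, 1.0
        return (2.0, 1.0) if m1 > m2 else (1.0, 2.0)
    m1, m2 = max(m1, 0.0), max(m2, 0.0)
    if m1 == 0.0 and m2 == 0.0:
        return 1.0, 1.0
    return m1, m2


def aggregate(cands: CandidateSet, sigma: float = SIGMA_DEFAULT) -> GrayImage:
    """Full aggregation: select top two, Sobel + Gaussian smoothing on each,
    metric-scaled weight assignment, pixel-wise blend.  Deterministic."""
    i, j = select_top_two(cands)
    img1, img2 = cands.images[i], cands.images[j]
    g1 = gaussian_edge_value(sobel_edge_map(img1), sigma)
    g2 = gaussian_edge_value(sobel_edge_map(img2), sigma)
    m1, m2 = _effective_scores(cands, i, j)
    w = assign_weights(g1, g2, m1, m2)
    return blend(img1, img2, w)
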