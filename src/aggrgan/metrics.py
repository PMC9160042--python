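"""The four image-quality metrics: SSIM, PSNR, histogram KL divergence, and
sharpness difference (SD).

All four operate on 8-bit images (peak intensity 255).  SSIM here is the
*global* single-window form — one mean, variance and covariance per image —
not the windowed variant common in imaging toolkits; a windowed flavour is
available behind a flag for comparison but is never the default.  Variance
and covariance use the population (1/N) estimator.

PSNR and SD are log-ratios that diverge for identical (or gradient-identical)
inputs; those cases return ``math.inf`` as an explicit sentinel that sorts
above every finite score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imaging import GrayImage

MAX_F = 255.0
#: conventional SSIM stabilizers (0.01 * 255)^2 and (0.03 * 255)^2
C1_DEFAULT = (0.01 * MAX_F) ** 2
C2_DEFAULT = (0.03 * MAX_F) ** 2
KL_EPS_DEFAULT = 1e-10


@dataclass(frozen=True)
class MetricReport:
    """Scores of one generated image against a reference."""

    ssim: float
    psnr: float
    kl: float
    sd: float

    def __post_init__(self):
        if self.ssim > 1.0 + 1e-12:
            raise ValueError(f"ssim {self.ssim} exceeds 1")
        if self.kl < -1e-12:
            raise ValueError(f"kl {self.kl} is negative")


@dataclass(frozen=True)
class Histogram:
    """A 256-bin intensity distribution (probabilities summing to one)."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.shape != (256,):
            raise ValueError(f"histogram must have 256 bins, got {p.shape}")
        if np.any(p < 0):
            raise ValueError("histogram probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"histogram sums to {p.sum()}, not 1")
        object.__setattr__(self, "probs", p)


def _check_pair(x: GrayImage, y: GrayImage) -> tuple[np.ndarray, np.ndarray]:
    if x.domain != "uint8" or y.domain != "uint8":
        raise ValueError("metrics are defined on uint8 images")
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x.astype_float(), y.astype_float()


def compute_ssim(x: GrayImage, y: GrayImage,
                 c1: float = C1_DEFAULT, c2: float = C2_DEFAULT) -> float:
    """Global structural similarity.

    SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2) /
           ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

    Exactly 1.0 for identical images.  Symmetric in its arguments.
    """
    if c1 <= 0 or c2 <= 0:
        raise ValueError("stabilizing constants c1, c2 must be positive")
    fx, fy = _check_pair(x, y)
    mx, my = fx.mean(), fy.mean()
    vx = ((fx - mx) ** 2).mean()
    vy = ((fy - my) ** 2).mean()
    cov = ((fx - mx) * (fy - my)).mean()
    num = (2.0 * mx * my + c1) * (2.0 * cov + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    return num / den


def compute_ssim_windowed(x: GrayImage, y: GrayImage, win: int = 7,
                          c1: float = C1_DEFAULT, c2: float = C2_DEFAULT) -> float:
    """Mean of the global SSIM over sliding win x win patches (non-default
    variant; kept for comparison against windowed toolkit implementations)."""
    fx, fy = _check_pair(x, y)
    m, n = fx.shape
    if win > min(m, n):
        raise ValueError(f"window {win} larger than image {x.shape}")
    vals = []
    for i in range(m - win + 1):
        for j in range(n - win + 1):
            vals.append(compute_ssim(
                GrayImage(x.pixels[i:i + win, j:j + win]),
                GrayImage(y.pixels[i:i + win, j:j + win]), c1, c2))
    return float(np.mean(vals))


def compute_mse(x: GrayImage, y: GrayImage) -> float:
    fx, fy = _check_pair(x, y)
    return float(((fx - fy) ** 2).mean())


def compute_psnr(x: GrayImage, y: GrayImage) -> float:
    """Peak signal-to-noise ratio, 20 log10(255 / sqrt(MSE)) dB; ``inf`` when
    the images are identical."""
    mse = compute_mse(x, y)
    if mse == 0.0:
        return math.inf
    return 20.0 * math.log10(MAX_F / math.sqrt(mse))


def image_histogram(x: GrayImage) -> Histogram:
    """Empirical distribution over the 256 intensity levels."""
    if x.domain != "uint8":
        raise ValueError("histograms are defined on uint8 images")
    counts = np.bincount(x.pixels.ravel(), minlength=256).astype(np.float64)
    return Histogram(counts / counts.sum())


def compute_kl(p: Histogram, q: Histogram, eps: float = KL_EPS_DEFAULT) -> float:
    """KL(P || Q) = sum_x P(x) log(P(x)/Q(x)) in nats.

    Both histograms get additive smoothing ``eps`` per bin (then renormalize)
    so empty bins — guaranteed in real images — do not blow up the log.
    Nonnegative by Gibbs' inequality; not symmetric.
    """
    if eps <= 0:
        raise ValueError("smoothing eps must be positive")
    ps = (p.probs + eps) / (p.probs + eps).sum()
    qs = (q.probs + eps) / (q.probs + eps).sum()
    return float(np.sum(ps * np.log(ps / qs)))


def _grad_map(f: np.ndarray) -> np.ndarray:
    """Discrete gradient 2 f(i,j) - f(i-1,j) - f(i,j-1) with replicate-border
    extension at the first row/column, so it is defined on the full grid."""
    up = np.vstack([f[:1, :], f[:-1, :]])
    left = np.hstack([f[:, :1], f[:, :-1]])
    return 2.0 * f - up - left


def compute_sd(x: GrayImage, y: GrayImage) -> float:
    """Sharpness difference: 10 log10(255^2 / grad_diff) dB where grad_diff is
    the mean absolute difference of the two discrete gradient maps; ``inf``
    when the gradients agree everywhere (e.g. two constant images)."""
    fx, fy = _check_pair(x, y)
    nabla = np.abs(_grad_map(fx) - _grad_map(fy)).mean()
    if nabla == 0.0:
        return math.inf
    return 10.0 * math.log10(MAX_F ** 2 / nabla)


def evaluate(generated: GrayImage, reference: GrayImage) -> MetricReport:
    """All four scores of ``generated`` against ``reference``."""
    return MetricReport(
        ssim=compute_ssim(generated, reference),
        psnr=compute_psnr(generated, reference),
        kl=compute_kl(image_histogram(generated), image_histogram(reference)),
        sd=compute_sd(generated, reference),
    )
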