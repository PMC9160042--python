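"""Deterministic brain-like grayscale phantoms.

Every other module is exercised against these synthetic slices, so no MRI
dataset is needed: an elliptical "head" of mid-gray tissue on a black
background, band-limited smooth texture inside the head, a bright circular
"tumor" blob, and optional additive Gaussian pixel noise.  The goal is the
statistical structure real slices have — plateaus, edges, non-trivial
histograms — not anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .imaging import GrayImage

BACKGROUND_LEVEL = 0
TISSUE_LEVEL = 110
TUMOR_LEVEL = 230


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of one phantom (fractions of ``size``)."""

    size: int = 64
    head_axes: tuple[float, float] = (0.42, 0.36)
    tumor_center: tuple[float, float] = (0.42, 0.60)
    tumor_radius: float = 0.10
    texture_scale: float = 12.0
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.size < 4:
            raise ValueError("phantom size must be at least 4")
        for frac in (*self.head_axes, *self.tumor_center):
            if not 0.0 < frac < 1.0:
                raise ValueError("head axes and tumor center must be fractions in (0,1)")
        if not 0.0 <= self.tumor_radius < 1.0:
            raise ValueError("tumor_radius must be a fraction in [0,1)")
        if self.texture_scale < 0 or self.noise_sd < 0:
            raise ValueError("texture_scale and noise_sd must be nonnegative")
        # the tumor disc must sit fully inside the head ellipse
        s = self.size
        cy, cx = s / 2.0, s / 2.0
        ay, ax = self.head_axes[0] * s, self.head_axes[1] * s
        ty, tx = self.tumor_center[0] * s, self.tumor_center[1] * s
        r = self.tumor_radius * s
        theta = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
        py = ty + r * np.sin(theta)
        px = tx + r * np.cos(theta)
        if np.any(((py - cy) / ay) ** 2 + ((px - cx) / ax) ** 2 > 1.0):
            raise ValueError("tumor disc extends outside the head ellipse")


def _masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    s = spec.size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cy = cx = s / 2.0
    ay, ax = spec.head_axes[0] * s, spec.head_axes[1] * s
    head = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    ty, tx = spec.tumor_center[0] * s, spec.tumor_center[1] * s
    r = spec.tumor_radius * s
    tumor = (yy - ty) ** 2 + (xx - tx) ** 2 <= r * r
    return head, tumor & head


def make_phantom(spec: PhantomSpec) -> GrayImage:
    """Render one phantom; bit-identical for identical specs.

    With texture_scale = 0 and noise_sd = 0 the image has exactly three
    intensity plateaus (background 0, tissue 110, tumor 230).
    """
    rng = np.random.default_rng(spec.seed)
    head, tumor = _masks(spec)
    img = np.zeros((spec.size, spec.size), dtype=np.float64)
    img[head] = TISSUE_LEVEL
    if spec.texture_scale > 0:
        raw = rng.standard_normal((spec.size, spec.size))
        tex = ndimage.gaussian_filter(raw, sigma=spec.size / 16.0, mode="reflect")
        sd = tex.std()
        if sd > 0:
            img[head & ~tumor] += (tex / sd * spec.texture_scale)[head & ~tumor]
    img[tumor] = TUMOR_LEVEL
    if spec.noise_sd > 0:
        img += rng.standard_normal(img.shape) * spec.noise_sd
    return GrayImage(np.rint(np.clip(img, 0, 255)).astype(np.uint8), "uint8")


def make_dataset(n: int, base: PhantomSpec | None = None, jitter: float = 0.1,
                 seed: int = 0) -> list[GrayImage]:
    """``n`` phantoms with tumor position/radius and texture jittered by the
    given relative fraction.  jitter = 0 yields ``n`` identical images."""
    if n < 1:
        raise ValueError("n must be at least 1")
    base = base if base is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        if jitter > 0:
            u = rng.uniform(-jitter, jitter, size=4)
            spec = replace(
                base,
                tumor_center=(base.tumor_center[0] * (1 + u[0]),
                              base.tumor_center[1] * (1 + u[1])),
                tumor_radius=base.tumor_radius * (1 + u[2]),
                texture_scale=base.texture_scale * (1 + u[3]),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        else:
            spec = base
        out.append(make_phantom(spec))
    return out


def region_means(img: GrayImage, spec: PhantomSpec) -> tuple[float, float, float]:
    """Mean intensity of (background, tissue, tumor) under the spec's masks."""
    head, tumor = _masks(spec)
    f = img.astype_float()
    return (float(f[~head].mean()), float(f[head & ~tumor].mean()),
            float(f[tumor].mean()) if tumor.any() else float("nan"))
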