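"""Grayscale image container, I/O and intensity-domain conversions.

Every stage of the pipeline exchanges :class:`GrayImage` objects.  Three
intensity conventions coexist: the quality metrics are defined on 8-bit
integers (peak intensity 255), GAN generators emit Tanh output in [-1, 1],
and the style-transfer optimizer works in [0, 1] floats.  ``convert`` maps
affinely between them; metrics refuse anything that is not uint8 so the
peak-signal constant is never silently wrong.

Coordinates are (row, col), 0-based, row 0 at the top — raster order, which
is also the grid the sharpness-difference gradient is defined on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

DOMAINS = ("uint8", "unit", "signed")
_RANGES = {"uint8": (0.0, 255.0), "unit": (0.0, 1.0), "signed": (-1.0, 1.0)}


@dataclass(frozen=True)
class GrayImage:
    """A 2-D intensity raster with a declared intensity domain."""

    pixels: np.ndarray
    domain: str = "uint8"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown intensity domain {self.domain!r}")
        if px.ndim != 2:
            raise ValueError(f"GrayImage must be 2-D, got shape {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"GrayImage must be at least 2x2, got {px.shape}")
        if self.domain == "uint8":
            px = px.astype(np.uint8) if px.dtype != np.uint8 else px
        else:
            px = px.astype(np.float64)
            if not np.all(np.isfinite(px)):
                raise ValueError("GrayImage contains non-finite values")
            lo, hi = _RANGES[self.domain]
            if px.min() < lo - 1e-9 or px.max() > hi + 1e-9:
                raise ValueError(
                    f"values [{px.min()}, {px.max()}] outside {self.domain} "
                    f"domain [{lo}, {hi}]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)


def load_image(path) -> GrayImage:
    """Read a raster file as 8-bit grayscale (RGB is converted to luminance)."""
    try:
        with Image.open(path) as im:
            im = im.convert("L")
            arr = np.asarray(im, dtype=np.uint8)
    except FileNotFoundError:
        raise IOError(f"cannot read image: no such file {path!s}") from None
    except Exception as exc:  # corrupt / undecodable
        raise IOError(f"cannot decode image {path!s}: {exc}") from exc
    return GrayImage(arr, "uint8")


def save_image(img: GrayImage, path) -> None:
    """Write as 8-bit grayscale PNG; lossless round trip with load_image."""
    u8 = convert(img, "uint8")
    Image.fromarray(u8.pixels, mode="L").save(path)


def extract_slices(volume_path, axis: int, indices: list[int]) -> list[GrayImage]:
    """Pull 2-D slices out of a NIfTI volume, min-max rescaled to uint8.

    A constant-valued slice (degenerate min == max) maps to all zeros.
    NIfTI support is optional at runtime: nibabel is imported lazily.
    """
    import nibabel as nib

    try:
        vol = np.asanyarray(nib.load(str(volume_path)).dataobj, dtype=np.float64)
    except FileNotFoundError:
        raise IOError(f"no such volume: {volume_path!s}") from None
    except Exception as exc:
        raise ValueError(f"not a readable NIfTI volume: {volume_path!s} ({exc})") from exc
    if not 0 <= axis < vol.ndim:
        raise IndexError(f"axis {axis} out of range for {vol.ndim}-D volume")
    depth = vol.shape[axis]
    out = []
    for idx in indices:
        if not 0 <= idx < depth:
            raise IndexError(f"slice index {idx} out of bounds for depth {depth}")
        sl = np.take(vol, idx, axis=axis)
        lo, hi = sl.min(), sl.max()
        if hi > lo:
            u8 = np.rint((sl - lo) / (hi - lo) * 255.0).astype(np.uint8)
        else:
            u8 = np.zeros_like(sl, dtype=np.uint8)
        out.append(GrayImage(u8, "uint8"))
    return out


def convert(img: GrayImage, target: str) -> GrayImage:
    """Affine map between intensity domains.

    Identity when target == source.  uint8 -> signed maps 0 to -1 and 255 to
    +1; the uint8 -> signed -> uint8 round trip is exact for all 256 levels.
    """
    if target not in DOMAINS:
        raise ValueError(f"unknown intensity domain {target!r}")
    if target == img.domain:
        return img
    # go through the unit interval
    px = img.astype_float()
    if img.domain == "uint8":
        unit = px / 255.0
    elif img.domain == "signed":
        unit = (px + 1.0) / 2.0
    else:
        unit = px
    if target == "unit":
        return GrayImage(np.clip(unit, 0.0, 1.0), "unit")
    if target == "signed":
        return GrayImage(np.clip(unit * 2.0 - 1.0, -1.0, 1.0), "signed")
    return GrayImage(np.rint(np.clip(unit, 0.0, 1.0) * 255.0).astype(np.uint8), "uint8")
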