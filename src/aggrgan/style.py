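"""Multi-layer neural style transfer for refining aggregated images.

The optimization variable is an image initialized at the *content* image
(the aggregated GAN output); the *style* image is the raw reference.  The
objective is

    L = w_cont * L_cont + w_sty * L_sty + w_tv * L_tv

with the content loss the half squared Euclidean distance between deep
feature maps at the content layer (4_2), the style loss a weighted sum of
squared Gram-matrix differences over the style layers (1_1 .. 5_1, each
weighted 1/5 and normalized by 1/(4 A_l^2 B_l^2)), and a total-variation
smoothness term.  Default loss weights are 5, 100 and 0.001 and the
optimizer is L-BFGS (history 10, strong-Wolfe line search) for up to 2000
iterations.

The feature extractor is a *contract*, not a fixed network: any object with
``layer_names`` and ``features(image_tensor) -> {name: Tensor}`` works.  The
default is a five-block convolutional stack (two 3x3 ReLU convolutions per
block, average pooling between blocks) with deterministic seeded random
weights, so the whole pipeline runs without downloading anything; a
VGG-19-style pretrained extractor can be plugged in through the same
contract.  The loss functions themselves are extractor-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .imaging import GrayImage, convert

STYLE_LAYERS = ("1_1", "2_1", "3_1", "4_1", "5_1")
CONTENT_LAYER = "4_2"


@dataclass(frozen=True)
class StyleConfig:
    w_cont: float = 5.0
    w_sty: float = 100.0
    w_tv: float = 0.001
    layer_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    iterations: int = 2000
    optimizer: str = "lbfgs"

    def __post_init__(self):
        if self.optimizer != "lbfgs":
            raise ValueError("only the lbfgs optimizer is supported")
        if len(self.layer_weights) != len(STYLE_LAYERS):
            raise ValueError("one layer weight per style layer required")
        if abs(sum(self.layer_weights) - 1.0) > 1e-9:
            raise ValueError("style layer weights must sum to 1")
        if self.iterations < 0:
            raise ValueError("iterations must be nonnegative")


class RandomConvExtractor:
    """Five-block convolutional feature extractor with seeded random weights.

    Layer ``i_j`` is the (post-ReLU) output of the j-th convolution of the
    i-th block; 2x2 average pooling sits between consecutive blocks.  He-
    scaled Gaussian weights keep activation magnitudes stable through the
    stack.  Deterministic per seed; never trained.
    """

    def __init__(self, seed: int = 0, widths: tuple[int, ...] = (8, 16, 16, 32, 32)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
        self.widths = widths
        self.convs: dict[str, nn.Conv2d] = {}
        c_in = 1
        for i, w in enumerate(widths, start=1):
            for j in (1, 2):
                scale = np.sqrt(2.0 / (c_in * 9))
                conv = nn.Conv2d(c_in, w, 3, rng, stride=1, pad=1, init_sd=scale)
                conv.w.requires_grad = False  # fixed features, never trained
                conv.b.requires_grad = False
                self.convs[f"{i}_{j}"] = conv
                c_in = w

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(self.convs.keys())

    def min_size(self) -> int:
        return 2 ** (len(self.widths) - 1)

    def features(self, img: Tensor,
                 layers: tuple[str, ...] | None = None) -> dict[str, Tensor]:
        """Map a (1, 1, H, W) image tensor to {layer_name: feature tensor}."""
        wanted = set(layers) if layers is not None else set(self.convs)
        missing = wanted - set(self.convs)
        if missing:
            raise ValueError(f"extractor has no layers {sorted(missing)}")
        out: dict[str, Tensor] = {}
        x = img
        deepest = max(int(k.split("_")[0]) for k in wanted)
        for i in range(1, deepest + 1):
            if i > 1:
                x = ag.avg_pool2d(x, 2)
            for j in (1, 2):
                name = f"{i}_{j}"
                x = ag.relu(self.convs[name](x))
                if name in wanted:
                    out[name] = x
        return out


# ---------------------------------------------------------------------------
# loss terms — generic over numpy arrays and autograd Tensors
# ---------------------------------------------------------------------------

def _as_stack(features):
    """Reshape a feature tensor/array of shape (1, C, H, W) or (C, B) to the
    (filters, positions) stack the Gram matrix is defined on."""
    n = features.shape
    if len(n) == 4:
        if n[0] != 1:
            raise ValueError("expected a single-image feature tensor")
        return features.reshape((n[1], n[2] * n[3]))
    if len(n) == 2:
        return features
    raise ValueError(f"cannot interpret feature shape {n}")


def gram_matrix(features):
    """G[i1, i2] = sum_k F[i1, k] F[i2, k]: the inner product between the
    vectorized feature maps of filters i1 and i2.  Symmetric PSD."""
    f = _as_stack(features)
    return f @ f.T


def content_loss(f, p):
    """Half squared Euclidean distance between two feature maps."""
    if f.shape != p.shape:
        raise ValueError(f"feature shapes differ: {f.shape} vs {p.shape}")
    d = f - p
    return 0.5 * (d * d).sum()


def style_loss(style_grams, gen_grams, dims, layer_weights):
    """Sum over layers of w_l / (4 A_l^2 B_l^2) * ||G_l - H_l||_F^2 where
    A_l is the filter count and B_l the spatial size of layer l."""
    if set(style_grams) != set(gen_grams) or set(style_grams) != set(dims):
        raise ValueError("style/generated Gram layer sets must match")
    total = None
    for name, w in zip(sorted(dims), layer_weights):
        a, b = dims[name]
        d = style_grams[name] - gen_grams[name]
        term = (w / (4.0 * a * a * b * b)) * (d * d).sum()
        total = term if total is None else total + term
    return total


def tv_loss(img):
    """Anisotropic squared total variation: the sum of squared horizontal and
    vertical neighbor differences.  Zero iff the image is constant."""
    if img.ndim == 4:
        dh = img[:, :, :, 1:] - img[:, :, :, :-1]
        dv = img[:, :, 1:, :] - img[:, :, :-1, :]
    else:
        dh = img[:, 1:] - img[:, :-1]
        dv = img[1:, :] - img[:-1, :]
    return (dh * dh).sum() + (dv * dv).sum()


def total_loss(parts, config: StyleConfig):
    """Weighted sum w_cont * L_cont + w_sty * L_sty + w_tv * L_tv."""
    cont, sty, tv = parts
    return config.w_cont * cont + config.w_sty * sty + config.w_tv * tv


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def _gram_and_dims(feats: dict[str, Tensor]):
    grams, dims = {}, {}
    for name, f in feats.items():
        stack = _as_stack(f)
        grams[name] = gram_matrix(stack)
        dims[name] = stack.shape
    return grams, dims


def run_style_transfer(content: GrayImage, style: GrayImage,
                       extractor=None, config: StyleConfig = StyleConfig(),
                       return_trace: bool = False):
    """Optimize an image (initialized at ``content``) so its deep content
    features match the content image and its Gram statistics match the style
    image.  Runs in unit-domain floats; the result is clamped to [0, 1] and
    converted back to uint8.  With ``iterations = 0`` the content image is
    returned unchanged."""
    if content.shape != style.shape:
        raise ValueError(f"content/style shape mismatch: {content.shape} vs {style.shape}")
    extractor = extractor if extractor is not None else RandomConvExtractor()
    shape = content.shape
    x0 = convert(content, "unit").pixels
    if config.iterations == 0:
        result = GrayImage(content.pixels.copy(), "uint8")
        return (result, [])if return_trace else result

    style_img = convert(style, "unit").pixels[None, None]
    content_img = x0[None, None]
    with np.errstate(all="ignore"):
        sfeats = extractor.features(Tensor(style_img), STYLE_LAYERS)
        target_grams, dims = _gram_and_dims(sfeats)
        target_grams = {k: Tensor(v.data) for k, v in target_grams.items()}
        cfeat = Tensor(
            extractor.features(Tensor(content_img), (CONTENT_LAYER,))[CONTENT_LAYER].data)

    trace: list[float] = []

    def objective(flat: np.ndarray):
        x = Tensor(flat.reshape((1, 1) + shape), requires_grad=True)
        feats = extractor.features(x, STYLE_LAYERS + (CONTENT_LAYER,))
        gen_grams, _ = _gram_and_dims({k: feats[k] for k in STYLE_LAYERS})
        l_cont = content_loss(feats[CONTENT_LAYER], cfeat)
        l_sty = style_loss(target_grams, gen_grams, dims, config.layer_weights)
        l_tv = tv_loss(x)
        loss = total_loss((l_cont, l_sty, l_tv), config)
        loss.backward()
        if not np.isfinite(loss.item()):
            raise FloatingPointError("non-finite style-transfer loss; aborting")
        trace.append(loss.item())
        return loss.item(), x.grad.ravel()

    res = minimize(objective, x0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": config.iterations, "maxcor": 10})
    final = np.clip(res.x.reshape(shape), 0.0, 1.0)
    result = convert(GrayImage(final, "unit"), "uint8")
    return (result, trace) if return_trace else result
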