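"""The three base generative models and their training loops.

* DCGAN-1 — convolutional generator that upsamples by nearest-neighbour
  interpolation followed by a 4x4 convolution at each resolution step.
* DCGAN-2 — identical in spirit but upsamples with 4x4 stride-2 transposed
  convolutions.
* WGAN-div — fully connected generator and critic trained with the
  Wasserstein-divergence objective
  L_DIV = E[f(x)] - E[f(x_hat)] + k E[||grad f(x_tilde)||^p],
  where x_tilde is a per-pair convex combination of real and fake samples
  and the gradient-norm penalty is differentiated through the critic
  parameters (double backprop).

Generators emit Tanh output in the signed domain; DCGAN discriminators end
in a sigmoid, the WGAN critic is an unbounded score.  Dropout 0.25 follows
every discriminator layer except the last; filters are 4x4 throughout;
optimizers are Adam (beta1 = 0.5).  All randomness — init, shuffling, latent
draws, dropout masks, interpolation coefficients — flows from the config
seed, so a training run is bit-reproducible.

Two named profiles ship: ``paper`` holds the full-scale settings
(batch/lr/epochs 64/2e-4/1000 for DCGAN-1, 128/2e-4/650 for DCGAN-2,
32/1e-3/1000 for WGAN-div); ``desk`` is the CPU-scale profile used by the
test suite (image size 32, 50 epochs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .imaging import GrayImage, convert

VARIANTS = ("dcgan1", "dcgan2", "wgan_div")
LOG_EPS = 1e-7


@dataclass(frozen=True)
class GanSpec:
    """Architecture description of one base model."""

    variant: str = "dcgan1"
    latent_dim: int = 100
    image_size: int = 32
    filter_size: int = 4
    leaky_slope: float = 0.2
    dropout: float = 0.25
    base_channels: int = 16  # width template; doubles per downsampling step

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        s = self.image_size
        if s < 16 or (s & (s - 1)) != 0:
            raise ValueError("image_size must be a power of two >= 16")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 2e-4
    epochs: int = 50
    optimizer: str = "adam"
    seed: int = 0
    k: float = 2.0
    p: float = 6.0

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.k <= 0 or self.p <= 0:
            raise ValueError("wgan-div k and p must be positive")


#: per-variant full-scale training settings
PAPER_CONFIGS = {
    "dcgan1": TrainConfig(batch_size=64, learning_rate=2e-4, epochs=1000),
    "dcgan2": TrainConfig(batch_size=128, learning_rate=2e-4, epochs=650),
    "wgan_div": TrainConfig(batch_size=32, learning_rate=1e-3, epochs=1000),
}
#: CPU-scale settings used for smoke training and the test suite
DESK_CONFIGS = {
    "dcgan1": TrainConfig(batch_size=64, learning_rate=2e-4, epochs=50),
    "dcgan2": TrainConfig(batch_size=64, learning_rate=2e-4, epochs=50),
    "wgan_div": TrainConfig(batch_size=32, learning_rate=1e-3, epochs=50),
}


def get_config(variant: str, profile: str = "desk", seed: int = 0) -> TrainConfig:
    table = {"paper": PAPER_CONFIGS, "desk": DESK_CONFIGS}[profile]
    return replace(table[variant], seed=seed)


@dataclass
class TrainLog:
    g_losses: list[float] = field(default_factory=list)
    d_losses: list[float] = field(default_factory=list)

    def append(self, g: float, d: float) -> None:
        if not (math.isfinite(g) and math.isfinite(d)):
            raise FloatingPointError(
                f"non-finite training loss (g={g}, d={d}); training aborted")
        self.g_losses.append(float(g))
        self.d_losses.append(float(d))


class Generator:
    """Callable wrapper: latent batch (N, latent_dim) -> signed images
    (N, 1, S, S)."""

    def __init__(self, net: nn.Module, spec: GanSpec):
        self.net = net
        self.spec = spec

    def parameters(self):
        return self.net.parameters()

    def __call__(self, z) -> Tensor:
        z = ag.as_tensor(z)
        out = self.net(z)
        if out.data.ndim == 2:  # fully connected path
            s = self.spec.image_size
            out = ag.reshape(out, (out.data.shape[0], 1, s, s))
        return out


class Critic:
    """Callable wrapper: image batch (N, 1, S, S) -> per-image score (N,)."""

    def __init__(self, net: nn.Module, spec: GanSpec):
        self.net = net
        self.spec = spec

    def parameters(self):
        return self.net.parameters()

    def __call__(self, x, rng=None, train: bool = True) -> Tensor:
        x = ag.as_tensor(x)
        if self.spec.variant == "wgan_div" and x.data.ndim == 4:
            x = ag.reshape(x, (x.data.shape[0], -1))
        out = self.net(x, rng=rng, train=train)
        return ag.reshape(out, (out.data.shape[0],))


def build_generator(spec: GanSpec, seed: int = 0) -> Generator:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    s, k, c = spec.image_size, spec.filter_size, spec.base_channels
    s0 = s // 8  # three doublings to reach full size
    pad_same = ((k - 1) // 2, k // 2)  # 'same' padding for even kernels
    if spec.variant == "dcgan1":
        net = nn.Sequential(
            nn.Dense(spec.latent_dim, 4 * c * s0 * s0, rng),
            nn.Reshape((4 * c, s0, s0)),
            nn.BatchNorm(4 * c), nn.LeakyReLU(spec.leaky_slope),
            nn.Upsample(2), nn.Conv2d(4 * c, 2 * c, k, rng, stride=1, pad=(pad_same, pad_same)),
            nn.BatchNorm(2 * c), nn.LeakyReLU(spec.leaky_slope),
            nn.Upsample(2), nn.Conv2d(2 * c, c, k, rng, stride=1, pad=(pad_same, pad_same)),
            nn.BatchNorm(c), nn.LeakyReLU(spec.leaky_slope),
            nn.Upsample(2), nn.Conv2d(c, c // 2, k, rng, stride=1, pad=(pad_same, pad_same)),
            nn.BatchNorm(c // 2), nn.LeakyReLU(spec.leaky_slope),
            nn.Conv2d(c // 2, 1, k, rng, stride=1, pad=(pad_same, pad_same)),
            nn.Tanh(),
        )
    elif spec.variant == "dcgan2":
        net = nn.Sequential(
            nn.Dense(spec.latent_dim, 4 * c * s0 * s0, rng),
            nn.Reshape((4 * c, s0, s0)),
            nn.BatchNorm(4 * c), nn.LeakyReLU(spec.leaky_slope),
            nn.ConvTranspose2d(4 * c, 2 * c, k, rng, stride=2, pad=1),
            nn.BatchNorm(2 * c), nn.LeakyReLU(spec.leaky_slope),
            nn.ConvTranspose2d(2 * c, c, k, rng, stride=2, pad=1),
            nn.BatchNorm(c), nn.LeakyReLU(spec.leaky_slope),
            nn.ConvTranspose2d(c, 1, k, rng, stride=2, pad=1),
            nn.Tanh(),
        )
    else:  # wgan_div: fully connected generator
        net = nn.Sequential(
            nn.Dense(spec.latent_dim, 128, rng), nn.LeakyReLU(spec.leaky_slope),
            nn.Dense(128, 256, rng), nn.LeakyReLU(spec.leaky_slope),
            nn.Dense(256, s * s, rng, scale=np.sqrt(1.0 / 256)), nn.Tanh(),
        )
    return Generator(net, spec)


def build_discriminator(spec: GanSpec, seed: int = 0) -> Critic:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    s, k, c = spec.image_size, spec.filter_size, spec.base_channels
    if spec.variant == "wgan_div":  # fully connected critic, unbounded output
        net = nn.Sequential(
            nn.Dense(s * s, 256, rng), nn.LeakyReLU(spec.leaky_slope),
            nn.Dense(256, 128, rng), nn.LeakyReLU(spec.leaky_slope),
            nn.Dense(128, 1, rng),
        )
    else:
        s3 = s // 8
        net = nn.Sequential(
            nn.Conv2d(1, c, k, rng, stride=2, pad=1),
            nn.LeakyReLU(spec.leaky_slope), nn.Dropout(spec.dropout),
            nn.Conv2d(c, 2 * c, k, rng, stride=2, pad=1),
            nn.BatchNorm(2 * c), nn.LeakyReLU(spec.leaky_slope), nn.Dropout(spec.dropout),
            nn.Conv2d(2 * c, 4 * c, k, rng, stride=2, pad=1),
            nn.BatchNorm(4 * c), nn.LeakyReLU(spec.leaky_slope), nn.Dropout(spec.dropout),
            nn.Flatten(),
            nn.Dense(4 * c * s3 * s3, 1, rng, scale=0.02),
            nn.Sigmoid(),
        )
    return Critic(net, spec)


# ---------------------------------------------------------------------------
# loss functions (array-level contracts; the training loop mirrors them in
# Tensor ops so gradients flow)
# ---------------------------------------------------------------------------

def vanilla_gan_loss(d_real, d_fake) -> tuple[float, float]:
    """Non-saturating minimax losses.

    d_loss = -mean log D(x) - mean log(1 - D(G(z)));
    g_loss = -mean log D(G(z))  (the generator maximizes the probability of
    the discriminator being wrong).  Probabilities are clamped away from
    {0, 1} by 1e-7 before the log.
    """
    dr = np.clip(np.asarray(d_real, dtype=np.float64), LOG_EPS, 1 - LOG_EPS)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), LOG_EPS, 1 - LOG_EPS)
    d_loss = float(-np.mean(np.log(dr)) - np.mean(np.log(1.0 - df)))
    g_loss = float(-np.mean(np.log(df)))
    return g_loss, d_loss


def minimax_value(d_real, d_fake) -> float:
    """The saturating two-player value E[log D(x)] + E[log(1 - D(G(z)))],
    exposed for completeness."""
    dr = np.clip(np.asarray(d_real, dtype=np.float64), LOG_EPS, 1 - LOG_EPS)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), LOG_EPS, 1 - LOG_EPS)
    return float(np.mean(np.log(dr)) + np.mean(np.log(1.0 - df)))


def wgan_div_loss(f_real, f_fake, grad_norms, k: float = 2.0, p: float = 6.0) -> float:
    """Wasserstein-divergence objective
    mean f(x) - mean f(x_hat) + k * mean(||grad f||^p)."""
    if k <= 0 or p <= 0:
        raise ValueError("k and p must be positive")
    fr = np.asarray(f_real, dtype=np.float64)
    ff = np.asarray(f_fake, dtype=np.float64)
    gn = np.asarray(grad_norms, dtype=np.float64)
    return float(fr.mean() - ff.mean() + k * np.mean(gn ** p))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _dataset_tensor(dataset: list[GrayImage], size: int) -> np.ndarray:
    if not dataset:
        raise ValueError("training dataset is empty")
    arrs = []
    for im in dataset:
        if im.shape != (size, size):
            raise ValueError(f"dataset image shape {im.shape} != spec size {size}")
        arrs.append(convert(im, "signed").pixels)
    return np.stack(arrs)[:, None, :, :]  # (N, 1, S, S)


def _log_t(x: Tensor) -> Tensor:
    return ag.log(x + LOG_EPS)


def train(spec: GanSpec, config: TrainConfig,
          dataset: list[GrayImage]) -> tuple[Generator, TrainLog]:
    """Alternating adversarial training (one discriminator step then one
    generator step per batch).  Returns the trained generator and the
    per-step loss log; epochs = 0 returns the untrained generator."""
    data = _dataset_tensor(dataset, spec.image_size)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    gen = build_generator(spec, seed=config.seed)
    dis = build_discriminator(spec, seed=config.seed)
    opt_g = nn.Adam(gen.parameters(), config.learning_rate)
    opt_d = nn.Adam(dis.parameters(), config.learning_rate)
    log = TrainLog()
    n = data.shape[0]
    bs = min(config.batch_size, n)
    wgan = spec.variant == "wgan_div"

    for _ in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, bs):
            real = Tensor(data[perm[start:start + bs]])
            nb = real.data.shape[0]

            # -- discriminator / critic step
            z = rng.standard_normal((nb, spec.latent_dim))
            with ag.no_grad():
                fake = gen(Tensor(z))  # detached from G
            if wgan:
                f_real = dis(real)
                f_fake = dis(fake)
                epsv = rng.uniform(0.0, 1.0, size=(nb, 1, 1, 1))
                x_mix = Tensor(epsv * real.data + (1 - epsv) * fake.data,
                               requires_grad=True)
                f_mix = dis(x_mix)
                (gx,) = ag.grad(f_mix.sum(), [x_mix], create_graph=True)
                gflat = ag.reshape(gx, (nb, -1))
                gnorm = ag.sqrt((gflat * gflat).sum(axis=1) + 1e-12)
                penalty = ag.tmean(ag.powt(gnorm, config.p))
                # critic maximizes mean f(real) - mean f(fake) - k * penalty
                d_loss = -(ag.tmean(f_real) - ag.tmean(f_fake)) \
                    + Tensor(config.k) * penalty
            else:
                d_real = dis(real, rng=rng, train=True)
                d_fake = dis(fake, rng=rng, train=True)
                d_loss = -ag.tmean(_log_t(d_real)) \
                    - ag.tmean(_log_t(Tensor(1.0) - d_fake))
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            # -- generator step
            z2 = rng.standard_normal((nb, spec.latent_dim))
            fake2 = gen(Tensor(z2))
            if wgan:
                g_loss = -ag.tmean(dis(fake2))
            else:
                g_loss = -ag.tmean(_log_t(dis(fake2, rng=rng, train=True)))
            opt_g.zero_grad()
            g_loss.backward()
            opt_g.step()

            log.append(g_loss.item(), d_loss.item())
    return gen, log


def sample(generator: Generator, n: int, seed: int = 0) -> list[GrayImage]:
    """Draw ``n`` images from standard-normal latents, converted to uint8."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    z = rng.standard_normal((n, generator.spec.latent_dim))
    with ag.no_grad():
        out = generator(Tensor(z)).data
    images = []
    for i in range(n):
        signed = np.clip(out[i, 0], -1.0, 1.0)
        images.append(convert(GrayImage(signed, "signed"), "uint8"))
    return images
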