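"""End-to-end orchestration: train the three base GANs, sample, aggregate,
stylize, evaluate, and emit the eight-method metric table.

The eight method variants reported per run are the three base models, each
base model followed by style transfer, and the edge-priority aggregate under
SSIM- and PSNR-based selection (both aggregates include the final style
transfer stage).  Each generated image is scored against the raw reference
it was paired with; table cells are means over the generated images, and
per-image scores plus the max statistic are written alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import gan
from .aggregation import CandidateSet, aggregate
from .imaging import GrayImage, load_image, save_image
from .metrics import MetricReport, compute_psnr, compute_ssim, evaluate
from .phantoms import PhantomSpec, make_dataset
from .style import RandomConvExtractor, StyleConfig, run_style_transfer

METHODS = (
    "dcgan1", "dcgan2", "wgan",
    "dcgan1+style", "dcgan2+style", "wgan+style",
    "aggrgan_ssim", "aggrgan_psnr",
)
COLUMNS = ("method", "ssim", "psnr", "kl", "sd")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run.  Exactly one data source: a directory of grayscale
    PNGs, or phantom generation parameters."""

    data_dir: str | None = None
    n_phantoms: int = 64
    image_size: int = 32
    gan_profile: str = "desk"
    agg_sigma: float = 1.0
    style: StyleConfig = field(default_factory=lambda: StyleConfig(iterations=100))
    out_dir: str = "aggrgan_run"
    seed: int = 0
    n_generated: int = 8

    def __post_init__(self):
        if self.gan_profile not in ("desk", "paper"):
            raise ValueError("gan_profile must be 'desk' or 'paper'")
        if self.n_generated < 1:
            raise ValueError("n_generated must be at least 1")


@dataclass
class EvaluationTable:
    """Mean metric scores per method, plus the per-image detail."""

    mean: pd.DataFrame
    per_image: pd.DataFrame
    max: pd.DataFrame


def _load_dataset(config: RunConfig) -> list[GrayImage]:
    if config.data_dir is not None:
        paths = sorted(Path(config.data_dir).glob("*.png"))
        if not paths:
            raise IOError(f"no PNG images found in {config.data_dir}")
        imgs = [load_image(p) for p in paths]
        for im in imgs:
            if im.shape != (config.image_size, config.image_size):
                raise ValueError(
                    f"image shape {im.shape} != configured size {config.image_size}")
        return imgs
    base = PhantomSpec(size=config.image_size)
    return make_dataset(config.n_phantoms, base=base, jitter=0.1, seed=config.seed)


def _report_row(method: str, idx: int, rep: MetricReport) -> dict:
    return {"method": method, "image": idx, "ssim": rep.ssim, "psnr": rep.psnr,
            "kl": rep.kl, "sd": rep.sd}


def run(config: RunConfig) -> EvaluationTable:
    """Execute the full flow and write report.csv, per_image.csv, PNGs and a
    manifest into ``config.out_dir``.  Fully reproducible per seed."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = _load_dataset(config)
    references = dataset[: config.n_generated]
    if len(references) < config.n_generated:
        raise ValueError("dataset smaller than n_generated")

    # --- stage 1: train the three base models and sample
    samples: dict[str, list[GrayImage]] = {}
    variant_keys = {"dcgan1": "dcgan1", "dcgan2": "dcgan2", "wgan_div": "wgan"}
    for variant, key in variant_keys.items():
        try:
            spec = gan.GanSpec(variant=variant, image_size=config.image_size)
            cfg = gan.get_config(variant, config.gan_profile, seed=config.seed)
            generator, _ = gan.train(spec, cfg, dataset)
            samples[key] = gan.sample(generator, config.n_generated,
                                      seed=config.seed)
        except Exception as exc:
            raise RuntimeError(f"stage 'train/{variant}' failed: {exc}") from exc

    extractor = RandomConvExtractor(seed=config.seed)
    rows: list[dict] = []
    images_out: dict[str, list[GrayImage]] = {m: [] for m in METHODS}

    for idx, ref in enumerate(references):
        base_imgs = {k: samples[k][idx] for k in ("dcgan1", "dcgan2", "wgan")}
        # --- stage 2: style transfer on each base output (style = raw ref)
        styled = {}
        for key, img in base_imgs.items():
            try:
                styled[key] = run_style_transfer(img, ref, extractor, config.style)
            except Exception as exc:
                raise RuntimeError(f"stage 'style/{key}' failed: {exc}") from exc
        # --- stage 3: aggregation under both selection metrics, then style
        aggs = {}
        for metric, fn in (("ssim", compute_ssim), ("psnr", compute_psnr)):
            try:
                cands = CandidateSet(
                    images=tuple(base_imgs.values()),
                    scores=tuple(fn(img, ref) for img in base_imgs.values()),
                    metric_name=metric,
                )
                fused = aggregate(cands, sigma=config.agg_sigma)
                aggs[f"aggrgan_{metric}"] = run_style_transfer(
                    fused, ref, extractor, config.style)
            except Exception as exc:
                raise RuntimeError(f"stage 'aggregate/{metric}' failed: {exc}") from exc
        # --- stage 4: evaluation against the paired reference
        produced = {**base_imgs,
                    **{f"{k}+style": v for k, v in styled.items()},
                    **aggs}
        for method in METHODS:
            img = produced[method]
            rows.append(_report_row(method, idx, evaluate(img, ref)))
            images_out[method].append(img)

    per_image = pd.DataFrame(rows)
    mean = (per_image.groupby("method", sort=False)[["ssim", "psnr", "kl", "sd"]]
            .mean().reindex(list(METHODS)).reset_index())
    mx = (per_image.groupby("method", sort=False)[["ssim", "psnr", "kl", "sd"]]
          .max().reindex(list(METHODS)).reset_index())
    table = EvaluationTable(mean=mean, per_image=per_image, max=mx)

    # --- persist everything needed to inspect or re-run
    write_report(table, out_dir / "report.csv")
    per_image.to_csv(out_dir / "per_image.csv", index=False)
    mx.to_csv(out_dir / "report_max.csv", index=False)
    for method, imgs in images_out.items():
        mdir = out_dir / "images" / method
        mdir.mkdir(parents=True, exist_ok=True)
        for idx, img in enumerate(imgs):
            save_image(img, mdir / f"{idx}.png")
    rdir = out_dir / "images" / "reference"
    rdir.mkdir(parents=True, exist_ok=True)
    for idx, img in enumerate(references):
        save_image(img, rdir / f"{idx}.png")
    manifest = asdict(config)
    manifest["methods"] = list(METHODS)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


def write_report(table: EvaluationTable | pd.DataFrame, path) -> None:
    """CSV with fixed column order (method, ssim, psnr, kl, sd); infinite
    sentinels serialize as ``inf``."""
    df = table.mean if isinstance(table, EvaluationTable) else table
    df = df.reindex(columns=list(COLUMNS))
    df.to_csv(path, index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path)
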