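"""Training loop: paired augmentation, two-time-scale Adam, checkpoints.

The recipe is a conditional-GAN standard: for each batch the two PatchGAN
discriminators are updated first on real and detached-fake pairs (learning
rate 1e-4), then the generator on the adversarial + feature-matching + color
objective (learning rate 2e-4), Adam betas (0.5, 0.999).  Geometric
augmentation (mirrors, rotations within +/-15 degrees, translations within
+/-20 px, each applied with probability 0.5 using one shared parameter draw
per pair) is followed by a resize to crop_size + 32 and a random crop.

Everything is driven by one seeded numpy Generator, so a run — including a
resumed run — is bit-reproducible on a single CPU.
"""

from __future__ import annotations

import io
import logging
import pickle
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .colorspace import GaussianKernel, gray_to_normalized_lab, normalize_lab, rgb_to_lab
from .discriminator import DiscriminatorConfig, PatchDiscriminator
from .generator import GeneratorOutput, NetworkConfig, TranslationGenerator
from .losses import (LossBundle, LossWeights, adversarial_loss, color_loss,
                     feature_matching_loss, total_generator_loss)
from .phantom import PairedSample, extract_roi, load_manifest

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "augment_pair", "sample_augment_params", "apply_augment",
    "train_step", "run_training", "save_checkpoint", "load_checkpoint",
    "build_models", "prepare_batch",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 1500
    batch_size: int = 8
    lr_g: float = 2e-4
    lr_d: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    augment_prob: float = 0.5
    crop_size: int = 256
    seed: int = 0
    checkpoint_every: int = 50
    max_steps: int | None = None
    blur_size: int = 21
    blur_sigma: float = 3.0
    alpha: float = 10.0
    beta: float = 0.001

    def __post_init__(self):
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be positive")
        if not 0.0 <= self.augment_prob <= 1.0:
            raise ValueError("augment_prob must lie in [0, 1]")

    @classmethod
    def desk(cls, seed: int = 42) -> "TrainConfig":
        """CPU-scale profile: 64-pixel crops, batch 4, 200 steps."""
        return cls(epochs=10_000, batch_size=4, crop_size=64, seed=seed,
                   checkpoint_every=1_000, max_steps=200, blur_size=9)

    def weights(self) -> LossWeights:
        return LossWeights(alpha=self.alpha, beta=self.beta)

    def kernel(self) -> GaussianKernel:
        return GaussianKernel(size=self.blur_size, sigma=self.blur_sigma)


# -- augmentation -----------------------------------------------------------

TRANSLATE_LIMIT_PX = 20.0
ROTATE_LIMIT_DEG = 15.0


def sample_augment_params(config: TrainConfig, rng: np.random.Generator,
                          image_size: int) -> dict:
    """Draw one shared parameter set for a pair (the transform log).

    Each geometric transform fires independently with probability
    ``augment_prob``; translations are simultaneous horizontal/vertical
    (diagonal) shifts bounded by +/-20 px, rotations by +/-15 degrees.
    """
    p = config.augment_prob
    params = {
        "hflip": bool(rng.random() < p),
        "vflip": bool(rng.random() < p),
        "rotate": float(rng.uniform(-ROTATE_LIMIT_DEG, ROTATE_LIMIT_DEG))
        if rng.random() < p else 0.0,
        "shift": tuple(rng.uniform(-TRANSLATE_LIMIT_PX, TRANSLATE_LIMIT_PX,
                                   size=2)) if rng.random() < p else (0.0, 0.0),
    }
    resized = config.crop_size + 32
    max_off = resized - config.crop_size
    if p == 0.0:  # augmentation off: deterministic center crop
        params["crop"] = (max_off // 2, max_off // 2)
    else:
        params["crop"] = (int(rng.integers(0, max_off + 1)),
                          int(rng.integers(0, max_off + 1)))
    return params


def _warp(img: np.ndarray, params: dict, crop_size: int, order: int) -> np.ndarray:
    if params["hflip"]:
        img = img[:, ::-1]
    if params["vflip"]:
        img = img[::-1]
    if params["rotate"] != 0.0:
        img = ndimage.rotate(img, params["rotate"], axes=(0, 1),
                             reshape=False, order=order, mode="nearest")
    if params["shift"] != (0.0, 0.0):
        shift = params["shift"] + (0.0,) * (img.ndim - 2)
        img = ndimage.shift(img, shift, order=order, mode="nearest")
    resized = crop_size + 32
    zoom = (resized / img.shape[0], resized / img.shape[1]) + (1.0,) * (img.ndim - 2)
    img = ndimage.zoom(img, zoom, order=order, mode="nearest",
                       grid_mode=True)
    r0, c0 = params["crop"]
    return np.ascontiguousarray(img[r0:r0 + crop_size, c0:c0 + crop_size])


def apply_augment(sample: PairedSample, params: dict,
                  crop_size: int) -> PairedSample:
    """Apply one shared transform draw to bmode, elastogram and mask."""
    bmode = np.clip(_warp(sample.bmode, params, crop_size, order=1), 0.0, 1.0)
    se = np.clip(_warp(sample.elastogram, params, crop_size, order=1), 0.0, 1.0)
    mask = _warp(sample.mask.astype(np.uint8), params, crop_size, order=0)
    return PairedSample(bmode=bmode, elastogram=se, mask=mask,
                        score=sample.score, id=sample.id)


def augment_pair(sample: PairedSample, config: TrainConfig,
                 rng: np.random.Generator) -> PairedSample:
    params = sample_augment_params(config, rng, sample.bmode.shape[0])
    return apply_augment(sample, params, config.crop_size)


# -- model assembly ---------------------------------------------------------

def build_models(net_cfg: NetworkConfig, seed: int
                 ) -> tuple[TranslationGenerator, PatchDiscriminator,
                            PatchDiscriminator]:
    """Xavier-initialised generator and the two scale discriminators.

    D1 (full frame) and D2 (ROI) share the architecture class and config but
    are drawn from distinct streams, so their parameters differ.
    """
    rng_g, rng_d1, rng_d2 = (np.random.default_rng(s)
                             for s in np.random.SeedSequence(seed).spawn(3))
    gen = TranslationGenerator(net_cfg, rng_g)
    # depth capped so the ROI discriminator keeps a >=2-pixel logit stage
    n_layers = min(4, max(2, int(np.log2(net_cfg.roi_size)) - 2))
    d_cfg = DiscriminatorConfig(n_layers=n_layers,
                                base_channels=net_cfg.base_channels)
    d1 = PatchDiscriminator(d_cfg, rng_d1)
    d2 = PatchDiscriminator(d_cfg, rng_d2)
    return gen, d1, d2


def prepare_batch(samples: list[PairedSample], roi_size: int
                  ) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor, nn.Tensor, list]:
    """Stack a batch into (x_global, y_global, x_roi, y_roi, windows)."""
    xg, yg, xr, yr, windows = [], [], [], [], []
    for s in samples:
        x_lab = gray_to_normalized_lab(s.bmode)
        y_lab = normalize_lab(rgb_to_lab(s.elastogram))
        _, window = extract_roi(s.bmode, s.mask, roi_size)
        (r0, r1), (c0, c1) = window
        xg.append(x_lab.transpose(2, 0, 1))
        yg.append(y_lab.transpose(2, 0, 1))
        xr.append(x_lab[r0:r1, c0:c1].transpose(2, 0, 1))
        yr.append(y_lab[r0:r1, c0:c1].transpose(2, 0, 1))
        windows.append(window)
    return (nn.Tensor(np.stack(xg)), nn.Tensor(np.stack(yg)),
            nn.Tensor(np.stack(xr)), nn.Tensor(np.stack(yr)), windows)


def train_step(batch: list[PairedSample], gen: TranslationGenerator,
               d1: PatchDiscriminator, d2: PatchDiscriminator,
               opt_g: nn.Adam, opt_d1: nn.Adam, opt_d2: nn.Adam,
               weights: LossWeights, kernel: GaussianKernel,
               batch_id: str = "?") -> LossBundle:
    """One D1/D2-then-G update on an already-augmented batch."""
    xg, yg, xr, yr, windows = prepare_batch(batch, gen.cfg.roi_size)

    out: GeneratorOutput = gen(xg, xr, windows)
    fake_g = nn.Tensor(out.global_out.data)   # detached copies for D updates
    fake_r = nn.Tensor(out.roi_out.data)

    bundle = LossBundle()
    for disc, opt, src, real, fake, key in (
            (d1, opt_d1, xg, yg, fake_g, "adv_d1"),
            (d2, opt_d2, xr, yr, fake_r, "adv_d2")):
        opt.zero_grad()
        logits_real, _ = disc(src, real)
        logits_fake, _ = disc(src, fake)
        loss_d = adversarial_loss(logits_real, logits_fake, "discriminator")
        loss_d.backward()
        opt.step()
        setattr(bundle, key, float(loss_d.data))

    # generator update: fresh discriminator passes through the live graph
    opt_g.zero_grad()
    for d in (d1, d2):
        d.zero_grad()
    logits_fake_g, feats_fake_g = d1(xg, out.global_out)
    logits_fake_r, feats_fake_r = d2(xr, out.roi_out)
    with_real = [(d1, xg, yg), (d2, xr, yr)]
    feats_real = []
    for d, src, real in with_real:
        _, fr = d(src, real)
        feats_real.append([nn.Tensor(f.data) for f in fr])  # detached

    adv_g = (adversarial_loss(None, logits_fake_g, "generator")
             + adversarial_loss(None, logits_fake_r, "generator"))
    fm1 = feature_matching_loss(feats_real[0], feats_fake_g)
    fm2 = feature_matching_loss(feats_real[1], feats_fake_r)
    col = color_loss(out.global_out, yg, kernel)
    total = total_generator_loss(adv_g, fm1, fm2, col, weights)
    if not np.isfinite(total.data):
        raise FloatingPointError(
            f"non-finite generator loss on batch {batch_id}: "
            f"adv={adv_g.data} fm=({fm1.data},{fm2.data}) color={col.data}")
    total.backward()
    opt_g.step()
    for d in (d1, d2):
        d.zero_grad()

    bundle.adv_g = float(adv_g.data)
    bundle.fm_d1 = float(fm1.data)
    bundle.fm_d2 = float(fm2.data)
    bundle.color = float(col.data)
    bundle.total_g = float(total.data)
    return bundle


# -- checkpointing ----------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path: str | Path, gen: TranslationGenerator,
                    d1: PatchDiscriminator, d2: PatchDiscriminator,
                    opt_g: nn.Adam, opt_d1: nn.Adam, opt_d2: nn.Adam,
                    rng: np.random.Generator, iteration: int,
                    net_cfg: NetworkConfig, train_cfg: TrainConfig) -> None:
    """Single-archive checkpoint: all parameters, optimizer moments,
    generator state of the RNG and both configs."""
    blob = {
        "version": CHECKPOINT_VERSION,
        "iteration": iteration,
        "net_cfg": asdict(net_cfg),
        "train_cfg": asdict(train_cfg),
        "gen": gen.state_dict(),
        "d1": d1.state_dict(),
        "d2": d2.state_dict(),
        "opt_g": opt_g.state_dict(),
        "opt_d1": opt_d1.state_dict(),
        "opt_d2": opt_d2.state_dict(),
        "rng_state": rng.bit_generator.state,
    }
    buf = io.BytesIO()
    pickle.dump(blob, buf, protocol=4)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> dict:
    blob = pickle.loads(Path(path).read_bytes())
    if blob.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version: {blob.get('version')}")
    blob["net_cfg"] = NetworkConfig(**blob["net_cfg"])
    tc = blob["train_cfg"]
    blob["train_cfg"] = TrainConfig(**tc)
    return blob


def restore_models(blob: dict) -> tuple[TranslationGenerator,
                                        PatchDiscriminator,
                                        PatchDiscriminator]:
    gen, d1, d2 = build_models(blob["net_cfg"], blob["train_cfg"].seed)
    gen.load_state_dict(blob["gen"])
    d1.load_state_dict(blob["d1"])
    d2.load_state_dict(blob["d2"])
    return gen, d1, d2


# -- orchestration ----------------------------------------------------------

def run_training(manifest: str | Path, train_cfg: TrainConfig,
                 net_cfg: NetworkConfig, out_dir: str | Path,
                 resume: str | Path | None = None) -> tuple[Path, Path]:
    """Epoch loop with seeded shuffling, CSV loss log and checkpoints.

    Returns (final checkpoint path, loss log path).  ``resume`` restarts
    from a saved checkpoint and continues the same random stream, so the
    subsequent steps reproduce an uninterrupted run exactly.
    """
    samples = load_manifest(manifest)
    if len(samples) < train_cfg.batch_size:
        raise ValueError("need at least one full batch of samples")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "loss_log.csv"

    if resume is not None:
        blob = load_checkpoint(resume)
        gen, d1, d2 = restore_models(blob)
        iteration = blob["iteration"]
        rng = np.random.default_rng(0)
        rng.bit_generator.state = blob["rng_state"]
        log_mode = "a"
    else:
        gen, d1, d2 = build_models(net_cfg, train_cfg.seed)
        iteration = 0
        rng = np.random.default_rng(train_cfg.seed)
        log_mode = "w"

    betas = (train_cfg.adam_beta1, train_cfg.adam_beta2)
    opt_g = nn.Adam(gen.parameters(), lr=train_cfg.lr_g, betas=betas)
    opt_d1 = nn.Adam(d1.parameters(), lr=train_cfg.lr_d, betas=betas)
    opt_d2 = nn.Adam(d2.parameters(), lr=train_cfg.lr_d, betas=betas)
    if resume is not None:
        opt_g.load_state_dict(blob["opt_g"])
        opt_d1.load_state_dict(blob["opt_d1"])
        opt_d2.load_state_dict(blob["opt_d2"])

    weights = train_cfg.weights()
    kernel = train_cfg.kernel()
    steps_per_epoch = len(samples) // train_cfg.batch_size
    start_epoch = iteration // steps_per_epoch

    with open(log_path, log_mode) as log:
        if log_mode == "w":
            log.write("iteration," + ",".join(LossBundle.FIELDS) + "\n")
        for epoch in range(start_epoch, train_cfg.epochs):
            order = rng.permutation(len(samples))
            for b in range(steps_per_epoch):
                idx = order[b * train_cfg.batch_size:
                            (b + 1) * train_cfg.batch_size]
                batch = [augment_pair(samples[i], train_cfg, rng)
                         for i in idx]
                bundle = train_step(
                    batch, gen, d1, d2, opt_g, opt_d1, opt_d2, weights,
                    kernel, batch_id=f"e{epoch}b{b}")
                iteration += 1
                log.write(f"{iteration}," + ",".join(
                    f"{v:.10g}" for v in bundle.row()) + "\n")
                if train_cfg.max_steps and iteration >= train_cfg.max_steps:
                    break
            if (epoch + 1) % train_cfg.checkpoint_every == 0:
                save_checkpoint(out_dir / f"checkpoint_{iteration:06d}.pkl",
                                gen, d1, d2, opt_g, opt_d1, opt_d2, rng,
                                iteration, net_cfg, train_cfg)
            if train_cfg.max_steps and iteration >= train_cfg.max_steps:
                break
        final = out_dir / "checkpoint_final.pkl"
        save_checkpoint(final, gen, d1, d2, opt_g, opt_d1, opt_d2, rng,
                        iteration, net_cfg, train_cfg)
    logger.info("training finished at iteration %d", iteration)
    return final, log_path
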