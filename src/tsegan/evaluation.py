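"""Image-quality metrics and model-level evaluation reports.

PSNR, SSIM and MSE operate on 8-bit renderings (dynamic range 255), the
domain in which clinical screenshots are compared.  SSIM is offered in two
modes: "global" evaluates the structural-similarity formula once with
whole-image moments; "windowed" (the default and the community convention)
averages it over 11x11 Gaussian-weighted local windows (sigma = 1.5).

``evaluate_model`` runs a checkpointed generator over a held-out manifest,
renders the normalized-Lab outputs back to 8-bit sRGB and reports the three
metrics plus the blue/green stiffness-ratio proxy inside the true nodule
mask.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .colorspace import denormalize_lab, lab_to_rgb
from .phantom import PairedSample, blue_green_ratio, load_manifest, score_from_ratio

logger = logging.getLogger(__name__)

__all__ = ["EvalConstants", "EvalReport", "psnr", "ssim", "mse",
           "evaluate_model", "render_output", "PSNR_CAP_DB"]

#: identical images have infinite PSNR; reported as this sentinel instead
PSNR_CAP_DB = 100.0


@dataclass(frozen=True)
class EvalConstants:
    """Dynamic range and the SSIM stabilizers derived from it."""

    max_intensity: float = 255.0
    k1: float = 0.01
    k2: float = 0.03

    @property
    def c1(self) -> float:
        return (self.k1 * self.max_intensity) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.max_intensity) ** 2


def _check_shapes(i: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    i = np.asarray(i, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if i.shape != g.shape:
        raise ValueError(f"shape mismatch: {i.shape} vs {g.shape}")
    return i, g


def mse(i: np.ndarray, g: np.ndarray) -> float:
    """Mean squared difference over H*W (multichannel: and channels)."""
    i, g = _check_shapes(i, g)
    return float(((i - g) ** 2).mean())


def psnr(i: np.ndarray, g: np.ndarray,
         constants: EvalConstants = EvalConstants()) -> float:
    """10 log10(MAX^2 / MSE) in dB; identical images return the cap."""
    err = mse(i, g)
    if err == 0.0:
        logger.debug("identical images: PSNR capped at %.0f dB", PSNR_CAP_DB)
        return PSNR_CAP_DB
    return float(10.0 * np.log10(constants.max_intensity ** 2 / err))


def ssim(i: np.ndarray, g: np.ndarray, mode: str = "windowed",
         constants: EvalConstants = EvalConstants()) -> float:
    """Structural similarity in [-1, 1].

    "global" uses whole-image means/variances/covariance (one evaluation of
    the formula); "windowed" averages local evaluations under an 11x11
    Gaussian window, sigma 1.5, cropping the half-window border.
    """
    i, g = _check_shapes(i, g)
    c1, c2 = constants.c1, constants.c2
    if mode == "global":
        mu_i, mu_g = i.mean(), g.mean()
        var_i, var_g = i.var(), g.var()
        cov = ((i - mu_i) * (g - mu_g)).mean()
        return float((2 * mu_i * mu_g + c1) * (2 * cov + c2)
                     / ((mu_i ** 2 + mu_g ** 2 + c1) * (var_i + var_g + c2)))
    if mode != "windowed":
        raise ValueError("mode must be 'global' or 'windowed'")
    if i.ndim == 3:
        return float(np.mean([ssim(i[..., c], g[..., c], "windowed", constants)
                              for c in range(i.shape[-1])]))
    sigma, truncate = 1.5, 3.5
    win = 2 * int(truncate * sigma + 0.5) + 1  # 11
    if win > min(i.shape):
        raise ValueError("window larger than image")

    def gf(x):
        return ndimage.gaussian_filter(x, sigma, truncate=truncate)

    mu_i, mu_g = gf(i), gf(g)
    var_i = gf(i * i) - mu_i ** 2
    var_g = gf(g * g) - mu_g ** 2
    cov = gf(i * g) - mu_i * mu_g
    num = (2 * mu_i * mu_g + c1) * (2 * cov + c2)
    den = (mu_i ** 2 + mu_g ** 2 + c1) * (var_i + var_g + c2)
    pad = win // 2
    return float((num / den)[pad:-pad, pad:-pad].mean())


@dataclass
class EvalReport:
    """Per-image metric rows plus arithmetic-mean aggregates."""

    model_id: str
    ids: list[str] = field(default_factory=list)
    psnr_values: list[float] = field(default_factory=list)
    ssim_values: list[float] = field(default_factory=list)
    mse_values: list[float] = field(default_factory=list)
    bg_ratios: list[float] = field(default_factory=list)
    proxy_scores: list[int] = field(default_factory=list)
    true_scores: list[int] = field(default_factory=list)

    @property
    def mean_psnr(self) -> float:
        return float(np.mean(self.psnr_values))

    @property
    def mean_ssim(self) -> float:
        return float(np.mean(self.ssim_values))

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.mse_values))

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "psnr_db", "ssim", "mse",
                        "blue_green_ratio", "proxy_score", "true_score"])
            for row in zip(self.ids, self.psnr_values, self.ssim_values,
                           self.mse_values, self.bg_ratios,
                           self.proxy_scores, self.true_scores):
                w.writerow(row)
            w.writerow(["mean", self.mean_psnr, self.mean_ssim,
                        self.mean_mse, float(np.mean(self.bg_ratios)),
                        "", ""])


def render_output(global_out: np.ndarray) -> np.ndarray:
    """Normalized-Lab (3, H, W) network output -> 8-bit sRGB H x W x 3."""
    lab = denormalize_lab(np.transpose(global_out, (1, 2, 0)))
    rgb = lab_to_rgb(lab)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def _fit_to(sample: PairedSample, size: int) -> PairedSample:
    """Deterministically resize a sample to the generator's frame size."""
    H = sample.bmode.shape[0]
    if H == size:
        return sample
    z = size / H
    bmode = np.clip(ndimage.zoom(sample.bmode, z, order=1, mode="nearest",
                                 grid_mode=True), 0, 1)
    se = np.clip(ndimage.zoom(sample.elastogram, (z, z, 1), order=1,
                              mode="nearest", grid_mode=True), 0, 1)
    mask = ndimage.zoom(sample.mask, z, order=0, mode="nearest",
                        grid_mode=True)
    return PairedSample(bmode, se, mask, sample.score, sample.id)


def evaluate_model(checkpoint: str | Path, manifest: str | Path,
                   out_csv: str | Path | None = None,
                   ssim_mode: str = "windowed") -> EvalReport:
    """Run a checkpointed generator over a manifest and score the outputs.

    Each B-mode frame is translated, rendered to 8-bit sRGB and compared to
    its ground-truth elastogram; the blue/green ratio is read inside the true
    nodule mask, and its fixed-band proxy score recorded next to the true
    score.  Unreadable manifest rows are skipped with a warning.
    """
    from .training import load_checkpoint, restore_models  # cycle guard

    blob = load_checkpoint(checkpoint)
    gen, _, _ = restore_models(blob)
    gen.eval()
    samples = load_manifest(manifest)
    report = EvalReport(model_id=str(checkpoint))
    for sample in samples:
        s = _fit_to(sample, gen.cfg.global_size)
        out = gen.translate(s.bmode, s.mask)
        fake = render_output(out.global_out.data[0])
        real = np.clip(np.round(s.elastogram * 255.0), 0, 255).astype(np.uint8)
        ratio = blue_green_ratio(fake / 255.0, s.mask)
        report.ids.append(s.id)
        report.psnr_values.append(psnr(real, fake))
        report.ssim_values.append(ssim(real, fake, ssim_mode))
        report.mse_values.append(mse(real, fake))
        report.bg_ratios.append(ratio)
        report.proxy_scores.append(score_from_ratio(ratio))
        report.true_scores.append(s.score)
    if not report.ids:
        raise ValueError("no evaluable samples")
    if out_csv is not None:
        report.write_csv(out_csv)
    return report
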