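"""Training objective: adversarial + feature-matching + Lab color losses.

All terms are evaluated on normalized-Lab images.  The adversarial term is
the conditional GAN binary cross-entropy (computed from raw logits through
log-sum-exp, never through an explicit sigmoid); the generator uses the
non-saturating variant.  Feature matching averages L1 distances of
discriminator stage features; the color loss compares Gaussian-blurred
images with the sum of squared plus absolute differences, so only smooth
color/brightness structure is penalised.  The total generator objective is

    L = L_GAN(D1) + L_GAN(D2) + alpha * (L_FM(D1) + L_FM(D2)) + beta * L_color

with alpha = 10 and beta = 0.001 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .colorspace import GaussianKernel

__all__ = [
    "LossWeights", "LossBundle", "adversarial_loss", "feature_matching_loss",
    "color_loss", "total_generator_loss",
]


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 10.0    # feature-matching weight
    beta: float = 0.001    # color-loss weight

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class LossBundle:
    """Named scalar losses for one optimisation step."""

    adv_d1: float = 0.0
    adv_d2: float = 0.0
    adv_g: float = 0.0
    fm_d1: float = 0.0
    fm_d2: float = 0.0
    color: float = 0.0
    total_g: float = 0.0

    FIELDS = ("adv_d1", "adv_d2", "adv_g", "fm_d1", "fm_d2", "color", "total_g")

    def row(self) -> list[float]:
        return [getattr(self, f) for f in self.FIELDS]


def _bce_with_logits(logits: nn.Tensor, target_ones: bool) -> nn.Tensor:
    """Mean binary cross-entropy from raw logits.

    softplus(-x) for target 1, softplus(x) for target 0; both forms are
    exact and overflow-free.
    """
    if logits.data.size == 0:
        raise ValueError("empty logit map")
    z = -logits if target_ones else logits
    return nn.softplus(z).mean()


def adversarial_loss(logits_real: nn.Tensor | None, logits_fake: nn.Tensor,
                     role: str) -> nn.Tensor:
    """Conditional-GAN BCE.

    role="discriminator": push real patches to 1 and fake patches to 0
    (requires both logit maps).  role="generator": non-saturating form,
    push fake patches to 1.
    """
    if role == "discriminator":
        if logits_real is None:
            raise ValueError("discriminator role needs real logits")
        return 0.5 * (_bce_with_logits(logits_real, True)
                      + _bce_with_logits(logits_fake, False))
    if role == "generator":
        return _bce_with_logits(logits_fake, True)
    raise ValueError("role must be 'discriminator' or 'generator'")


def feature_matching_loss(features_real: list[nn.Tensor],
                          features_fake: list[nn.Tensor]) -> nn.Tensor:
    """Sum over stages of (L1 distance / element count of the stage)."""
    if len(features_real) != len(features_fake):
        raise ValueError("feature lists differ in length")
    total = None
    for fr, ff in zip(features_real, features_fake):
        if fr.shape != ff.shape:
            raise ValueError("feature shape mismatch")
        term = (fr - ff).abs().sum() * (1.0 / fr.data.size)
        total = term if total is None else total + term
    return total


def color_loss(x: nn.Tensor, y: nn.Tensor,
               kernel: GaussianKernel | None = None) -> nn.Tensor:
    """Blur both images, then summed squared plus summed absolute difference.

    Operates on (N, C, H, W) tensors; the blur uses reflect padding so a
    constant image passes through unchanged.  Sums (not means) over all
    elements — the small default beta assumes this scale.
    """
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    kernel = kernel or GaussianKernel()
    k = min(kernel.size, (min(x.shape[2], x.shape[3]) // 2) * 2 + 1)
    if k != kernel.size:  # shrink for images smaller than the kernel
        kernel = GaussianKernel(size=k, sigma=kernel.sigma)
    diff = nn.depthwise_conv2d(x, kernel.weights) - nn.depthwise_conv2d(
        y, kernel.weights)
    return (diff ** 2.0).sum() + diff.abs().sum()


def total_generator_loss(adv_g: nn.Tensor, fm_d1: nn.Tensor, fm_d2: nn.Tensor,
                         color: nn.Tensor, weights: LossWeights) -> nn.Tensor:
    """adv_g (already summed over discriminators) + alpha*FM + beta*color."""
    return adv_g + weights.alpha * (fm_d1 + fm_d2) + weights.beta * color
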