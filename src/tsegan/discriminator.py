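"""Conditional PatchGAN discriminators.

A single architecture serves both scales: D1 judges full-resolution
(B-mode, elastogram) pairs, D2 the 128-pixel ROI pairs; they share code and
differ only in their independently initialised parameters.  Each applies a
stack of strided 4x4 convolutions to the channel-concatenated source/target
pair and emits a grid of patch logits (no sigmoid — the stable
binary-cross-entropy loss consumes raw logits), exposing every intermediate
feature map for the feature-matching loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["DiscriminatorConfig", "PatchDiscriminator"]


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Depth/width of one PatchGAN; defaults give the 70x70 receptive field."""

    n_layers: int = 4
    base_channels: int = 64
    in_channels: int = 6  # source (3) + target (3), both normalized Lab

    def __post_init__(self):
        if self.n_layers < 2:
            raise ValueError("feature matching needs at least 2 stages")


class PatchDiscriminator(nn.Module):
    def __init__(self, config: DiscriminatorConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        ch = config.base_channels
        self.stages = []
        cin = config.in_channels
        for i in range(config.n_layers):
            conv = nn.Conv2d(cin, ch, 4, rng, stride=2, pad=1)
            bn = nn.BatchNorm2d(ch) if i > 0 else None
            self.stages.append((conv, bn))
            setattr(self, f"conv{i}", conv)
            if bn is not None:
                setattr(self, f"bn{i}", bn)
            cin, ch = ch, ch * 2
        self.out_conv = nn.Conv2d(cin, 1, 4, rng, stride=1, pad=1)

    def forward(self, source: nn.Tensor, target: nn.Tensor
                ) -> tuple[nn.Tensor, list[nn.Tensor]]:
        """Return (patch logits, list of the n_layers stage features)."""
        if source.shape[2:] != target.shape[2:]:
            raise ValueError("source/target resolution mismatch")
        h = nn.concat([source, target], axis=1)
        features: list[nn.Tensor] = []
        for conv, bn in self.stages:
            h = conv(h)
            if bn is not None:
                h = bn(h)
            h = h.leaky_relu(0.2)
            features.append(h)
        logits = self.out_conv(h)
        return logits, features
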