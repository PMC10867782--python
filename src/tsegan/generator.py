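"""Global-to-local translation generator.

Three cooperating parts turn a 256x256 B-mode frame (as a zero-chroma
normalized-Lab tensor) into a color elastogram:

* a **local generator** on the 128x128 nodule ROI — deformable-convolution
  encoder (large 7x7 first kernel, 3x3 afterwards), nine residual fusion
  blocks, and a SPADE decoder whose modulation maps are predicted from the
  encoder skips and the raw ROI;
* a **global generator** on the full frame — spatial-attention encoder whose
  bottleneck receives the local decoder features summed into the ROI window,
  nine residual blocks, transposed-convolution decoder;
* a **content revisor** that splits the output into n-1 foreground content
  masks plus the input background and recombines them with channel-attention
  weights, so untranslated background is preserved exactly when its weight
  saturates.

Deformable convolutions let the receptive field follow the nodule's
compression-induced deformation; their offset heads are zero-initialised, so
training starts from plain convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .colorspace import gray_to_normalized_lab
from .phantom import extract_roi

__all__ = [
    "NetworkConfig", "MaskBundle", "GeneratorOutput", "SpadeBlock",
    "SpadeResBlock", "ResidualBlock", "ResidualFusion", "SpatialAttention",
    "DeformResBlock", "LocalGenerator", "GlobalGenerator", "ContentRevisor",
    "TranslationGenerator", "fuse_features", "standardize_channels",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``desk()`` gives the reduced profile (8 base channels, 64-pixel frames)
    used for CPU-scale training and testing.
    """

    base_channels: int = 64
    n_downsamples_global: int = 2
    n_downsamples_local: int = 2
    n_resblocks: int = 9
    n_groups: int = 4
    roi_size: int = 128
    global_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2 (foreground + background)")
        if self.global_size != 2 * self.roi_size:
            raise ValueError("global_size must equal 2 x roi_size")

    @classmethod
    def desk(cls, seed: int = 0) -> "NetworkConfig":
        return cls(base_channels=8, roi_size=32, global_size=64, seed=seed)


@dataclass
class MaskBundle:
    """Content masks and attention weights of the content revisor."""

    content_masks: np.ndarray      # (N, n-1, 3, H, W) in (-1, 1)
    attention_weights: np.ndarray  # (N, n), rows sum to 1

    def validate(self) -> "MaskBundle":
        if not np.allclose(self.attention_weights.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("attention weights must sum to 1")
        return self


@dataclass
class GeneratorOutput:
    """Everything one forward pass produces."""

    global_out: nn.Tensor          # (N, 3, G, G) in (-1, 1)
    roi_out: nn.Tensor             # (N, 3, R, R) in (-1, 1)
    masks: MaskBundle | None
    roi_windows: list[tuple]


def standardize_channels(x: nn.Tensor, eps: float = 1e-5) -> nn.Tensor:
    """Parameter-free per-channel, per-sample spatial standardization."""
    mu = x.mean(axis=(2, 3), keepdims=True)
    var = ((x - mu) ** 2.0).mean(axis=(2, 3), keepdims=True)
    return (x - mu) * (var + eps) ** -0.5


class SpadeBlock(nn.Module):
    """Spatially-adaptive denormalization -> activation -> convolution.

    The feature map is standardized per channel, then modulated by gamma/beta
    maps predicted from the conditioning stack (skip features concatenated
    with the raw input resized to this resolution).
    """

    def __init__(self, channels: int, cond_channels: int,
                 rng: np.random.Generator, hidden: int | None = None):
        super().__init__()
        hidden = hidden or max(channels // 2, 8)
        self.shared = nn.Conv2d(cond_channels, hidden, 3, rng)
        self.to_gamma = nn.Conv2d(hidden, channels, 3, rng)
        self.to_beta = nn.Conv2d(hidden, channels, 3, rng)
        self.conv = nn.Conv2d(channels, channels, 3, rng)

    def denormalize(self, x: nn.Tensor, cond: nn.Tensor) -> nn.Tensor:
        if x.shape[2:] != cond.shape[2:]:
            raise ValueError("conditioning resolution mismatch")
        h = self.shared(cond).relu()
        gamma = self.to_gamma(h)
        beta = self.to_beta(h)
        return standardize_channels(x) * (1.0 + gamma) + beta

    def forward(self, x: nn.Tensor, cond: nn.Tensor) -> nn.Tensor:
        return self.conv(self.denormalize(x, cond).relu())


class SpadeResBlock(nn.Module):
    """Two SPADE blocks with a shortcut connection."""

    def __init__(self, channels: int, cond_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.block1 = SpadeBlock(channels, cond_channels, rng)
        self.block2 = SpadeBlock(channels, cond_channels, rng)

    def forward(self, x: nn.Tensor, cond: nn.Tensor) -> nn.Tensor:
        h = self.block1(x, cond)
        h = self.block2(h, cond)
        return x + h


class ResidualBlock(nn.Module):
    """Standard 3x3 conv-norm-ReLU x2 residual block."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, rng)
        self.bn1 = nn.BatchNorm2d(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return x + h


class ResidualFusion(nn.Module):
    """A chain of residual blocks at constant resolution."""

    def __init__(self, channels: int, n_blocks: int, rng: np.random.Generator):
        super().__init__()
        self.blocks = [ResidualBlock(channels, rng) for _ in range(n_blocks)]
        for i, b in enumerate(self.blocks):
            setattr(self, f"b{i}", b)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class DeformResBlock(nn.Module):
    """Two deformable convolution blocks (conv + offset head + BN +
    LeakyReLU) with a shortcut; the first convolution may stride."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        self.dc1 = nn.DeformConv2d(cin, cout, 3, rng, stride=stride)
        self.bn1 = nn.BatchNorm2d(cout)
        self.dc2 = nn.DeformConv2d(cout, cout, 3, rng)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.shortcut = nn.Conv2d(cin, cout, 1, rng, stride=stride, pad=0)
        else:
            self.shortcut = None

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.bn1(self.dc1(x)).leaky_relu(0.2)
        h = self.bn2(self.dc2(h))
        s = x if self.shortcut is None else self.shortcut(x)
        return (s + h).leaky_relu(0.2)


class SpatialAttention(nn.Module):
    """Channel-pooled 7x7-conv sigmoid mask multiplied onto the input."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, 7, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        mask = self.conv(nn.concat([avg, mx], axis=1)).sigmoid()
        return x * mask


class LocalEncoder(nn.Module):
    """7x7 deformable stem plus strided deformable residual blocks.

    Returns the bottleneck features and the per-resolution skip maps
    (full, half, ... resolution) for the SPADE decoder.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        base = cfg.base_channels
        self.stem = nn.DeformConv2d(3, base, 7, rng)
        self.stem_bn = nn.BatchNorm2d(base)
        self.blocks = []
        ch = base
        for i in range(cfg.n_downsamples_local):
            blk = DeformResBlock(ch, ch * 2, rng, stride=2)
            self.blocks.append(blk)
            setattr(self, f"down{i}", blk)
            ch *= 2
        self.out_channels = ch

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, list[nn.Tensor]]:
        h = self.stem_bn(self.stem(x)).leaky_relu(0.2)
        skips = [h]
        for blk in self.blocks:
            h = blk(h)
            skips.append(h)
        return h, skips[:-1]


def _avg_pool(x: nn.Tensor, factor: int) -> nn.Tensor:
    if factor == 1:
        return x
    N, C, H, W = x.shape
    return x.reshape(N, C, H // factor, factor, W // factor, factor).mean(
        axis=(3, 5))


class LocalGenerator(nn.Module):
    """ROI branch: deformable encoder -> residual fusion -> SPADE decoder.

    ``forward`` returns the tanh-bounded ROI elastogram and the decoder
    feature map just before the output convolution (``fusion_features``),
    which the global branch sums into its bottleneck.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.encoder = LocalEncoder(cfg, rng)
        ch = self.encoder.out_channels
        self.fusion = ResidualFusion(ch, cfg.n_resblocks, rng)
        self.ups = []
        self.spades = []
        for i in range(cfg.n_downsamples_local):
            up = nn.ConvTranspose2d(ch, ch // 2, rng)
            ch //= 2
            # conditioning: encoder skip at target resolution + raw ROI
            spade = SpadeResBlock(ch, ch + 3, rng)
            self.ups.append(up)
            self.spades.append(spade)
            setattr(self, f"up{i}", up)
            setattr(self, f"spade{i}", spade)
        self.out_conv = nn.Conv2d(ch, 3, 7, rng)

    def forward(self, roi: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        if roi.shape[2] != self.cfg.roi_size or roi.shape[3] != self.cfg.roi_size:
            raise ValueError(f"expected {self.cfg.roi_size}-pixel ROI input")
        h, skips = self.encoder(roi)
        h = self.fusion(h)
        for up, spade, skip in zip(self.ups, self.spades, reversed(skips)):
            h = up(h)
            raw = _avg_pool(roi, roi.shape[2] // h.shape[2])
            h = spade(h, nn.concat([skip, raw], axis=1))
        fusion_features = h
        out = self.out_conv(fusion_features).tanh()
        return out, fusion_features


def fuse_features(global_encoded: nn.Tensor, fusion_features: nn.Tensor,
                  roi_windows: list[tuple], downsample_factor: int,
                  projection: nn.Module) -> nn.Tensor:
    """Sum ROI-branch features into the global bottleneck at the ROI window.

    The local decoder features are projected to the global channel count,
    average-pooled to the window's footprint at the encoder resolution, and
    embedded in zeros at the (scaled) window position of each sample, so the
    element-wise sum respects the spatial registration of the two branches.
    """
    N, C, Hg, Wg = global_encoded.shape
    pooled = _avg_pool(projection(fusion_features), downsample_factor)
    ph, pw = pooled.shape[2], pooled.shape[3]
    embedded = []
    for i, ((r0, r1), (c0, c1)) in enumerate(roi_windows):
        rs, cs = r0 // downsample_factor, c0 // downsample_factor
        if rs < 0 or rs + ph > Hg or cs < 0 or cs + pw > Wg:
            raise ValueError("ROI window outside the global feature bounds")
        patch = pooled[i:i + 1]
        embedded.append(nn.pad2d(patch, (rs, Hg - rs - ph, cs, Wg - cs - pw)))
    return global_encoded + nn.concat(embedded, axis=0)


class GlobalGenerator(nn.Module):
    """Full-frame branch with spatial attention and local-feature fusion."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        base = cfg.base_channels
        self.stem = nn.Conv2d(3, base, 7, rng)
        self.stem_bn = nn.BatchNorm2d(base)
        self.attention = SpatialAttention(rng)
        self.downs = []
        ch = base
        for i in range(cfg.n_downsamples_global):
            conv = nn.Conv2d(ch, ch * 2, 3, rng, stride=2)
            bn = nn.BatchNorm2d(ch * 2)
            self.downs.append((conv, bn))
            setattr(self, f"down{i}", conv)
            setattr(self, f"dbn{i}", bn)
            ch *= 2
        self.bottleneck_channels = ch
        # 1x1 projection of local decoder features onto the global channels
        self.local_proj = nn.Conv2d(base, ch, 1, rng, pad=0)
        self.fusion = ResidualFusion(ch, cfg.n_resblocks, rng)
        self.ups = []
        for i in range(cfg.n_downsamples_global):
            up = nn.ConvTranspose2d(ch, ch // 2, rng)
            bn = nn.BatchNorm2d(ch // 2)
            self.ups.append((up, bn))
            setattr(self, f"up{i}", up)
            setattr(self, f"ubn{i}", bn)
            ch //= 2

    def encode(self, x: nn.Tensor) -> nn.Tensor:
        h = self.stem_bn(self.stem(x)).leaky_relu(0.2)
        h = self.attention(h)
        for conv, bn in self.downs:
            h = bn(conv(h)).leaky_relu(0.2)
        return h

    def decode(self, h: nn.Tensor) -> nn.Tensor:
        for up, bn in self.ups:
            h = bn(up(h)).relu()
        return h

    def forward(self, x: nn.Tensor, fusion_features: nn.Tensor,
                roi_windows: list[tuple]) -> nn.Tensor:
        h = self.encode(x)
        h = fuse_features(h, fusion_features, roi_windows,
                          2 ** self.cfg.n_downsamples_global, self.local_proj)
        h = self.fusion(h)
        return self.decode(h)


class ContentRevisor(nn.Module):
    """Foreground/background recomposition head.

    From the global decoder features m it derives n-1 tanh content masks and
    an n-way channel-attention distribution (global average + max pooling
    through a shared fully-connected layer, softmax over the n groups); the
    output is the attention-weighted sum of the content masks plus the raw
    input weighted by the background attention.
    """

    def __init__(self, channels: int, n_groups: int, rng: np.random.Generator):
        super().__init__()
        if n_groups < 2:
            raise ValueError("need at least 2 groups")
        self.n = n_groups
        self.content_conv = nn.Conv2d(channels, 3 * (n_groups - 1), 3, rng)
        self.attn_conv = nn.Conv2d(channels, n_groups, 3, rng)
        self.fc = nn.Linear(n_groups, n_groups, rng)

    def forward(self, m: nn.Tensor, x: nn.Tensor
                ) -> tuple[nn.Tensor, MaskBundle]:
        N, _, H, W = m.shape
        n = self.n
        content = self.content_conv(m).tanh()          # (N, 3(n-1), H, W)
        masks = content.reshape(N, n - 1, 3, H, W)

        a_mid = self.attn_conv(m)                      # (N, n, H, W)
        pooled = self.fc(a_mid.mean(axis=(2, 3))) + self.fc(
            a_mid.reshape(N, n, H * W).max(axis=2))
        # softmax over the n groups (per sample)
        shifted = pooled - pooled.data.max(axis=1, keepdims=True)
        expd = shifted.exp()
        attn = expd * expd.sum(axis=1, keepdims=True) ** -1.0   # (N, n)

        fg_w = attn[:, :n - 1].reshape(N, n - 1, 1, 1, 1)
        bg_w = attn[:, n - 1:].reshape(N, 1, 1, 1)
        out = (masks * fg_w).sum(axis=1) + x * bg_w
        bundle = MaskBundle(content_masks=masks.data.copy(),
                            attention_weights=attn.data.copy())
        return out, bundle


class TranslationGenerator(nn.Module):
    """The full three-part generator.

    ``forward`` consumes batched normalized-Lab tensors; ``translate`` is the
    numpy convenience path from a grayscale B-mode frame and nodule mask.
    """

    def __init__(self, cfg: NetworkConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng(cfg.seed)
        self.local = LocalGenerator(cfg, rng)
        self.global_gen = GlobalGenerator(cfg, rng)
        self.revisor = ContentRevisor(cfg.base_channels, cfg.n_groups, rng)

    def forward(self, x: nn.Tensor, rois: nn.Tensor,
                roi_windows: list[tuple]) -> GeneratorOutput:
        roi_out, fusion_features = self.local(rois)
        m = self.global_gen(x, fusion_features, roi_windows)
        global_out, bundle = self.revisor(m, x)
        return GeneratorOutput(global_out=global_out, roi_out=roi_out,
                               masks=bundle, roi_windows=roi_windows)

    def prepare_inputs(self, bmode: np.ndarray, mask: np.ndarray
                       ) -> tuple[nn.Tensor, nn.Tensor, list[tuple]]:
        """Grayscale frame + mask -> (global tensor, ROI tensor, windows)."""
        if bmode.shape != (self.cfg.global_size, self.cfg.global_size):
            raise ValueError(
                f"expected a {self.cfg.global_size}-pixel grayscale frame")
        lab = gray_to_normalized_lab(bmode)            # H x W x 3
        roi_lab, window = extract_roi(lab, mask, self.cfg.roi_size)
        x = nn.Tensor(lab.transpose(2, 0, 1)[None])
        roi = nn.Tensor(roi_lab.transpose(2, 0, 1)[None])
        return x, roi, [window]

    def translate(self, bmode: np.ndarray, mask: np.ndarray) -> GeneratorOutput:
        x, roi, windows = self.prepare_inputs(bmode, mask)
        return self.forward(x, roi, windows)
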