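"""sRGB <-> CIELAB conversion, Lab tensor normalization, Gaussian blur and
channel-distribution diagnostics.

Elastograms carry their clinical information almost entirely in color
(blue = stiff, green = soft), and the opponent axes a (green-red) and
b (blue-yellow) of CIELAB separate that information from luminance.  All
network arithmetic therefore happens on Lab images affinely mapped to
[-1, 1] per channel.

Conversions use the D65 illuminant / 2-degree observer convention of sRGB
(delegated to scikit-image); luminance L lives in [0, 100], the opponent
channels nominally in [-128, 127].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor

logger = logging.getLogger(__name__)

__all__ = [
    "LabImage", "GaussianKernel", "rgb_to_lab", "lab_to_rgb",
    "normalize_lab", "denormalize_lab", "gaussian_blur", "channel_entropy",
    "gray_to_normalized_lab",
]

# affine normalization constants: L in [0,100]; a,b nominal [-128,127]
_L_SCALE, _L_SHIFT = 50.0, 50.0
_AB_SCALE, _AB_SHIFT = 127.5, -0.5


@dataclass
class LabImage:
    """CIELAB image as three H x W channel planes."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def stack(self) -> np.ndarray:
        return np.stack([self.L, self.a, self.b], axis=-1)

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "LabImage":
        return cls(arr[..., 0], arr[..., 1], arr[..., 2])


@dataclass
class GaussianKernel:
    """Normalized, 90-degree-symmetric 2-D Gaussian kernel."""

    size: int = 21
    sigma: float = 3.0
    weights: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.size % 2 == 0 or self.size < 1:
            raise ValueError("kernel size must be odd and positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        half = self.size // 2
        ax = np.arange(-half, half + 1, dtype=np.float64)
        g1 = np.exp(-(ax ** 2) / (2.0 * self.sigma ** 2))
        k = np.outer(g1, g1)
        self.weights = k / k.sum()


def rgb_to_lab(rgb: np.ndarray) -> LabImage:
    """Convert an H x W x 3 sRGB array in [0, 1] to CIELAB (D65)."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an HxWx3 array")
    if rgb.min() < -1e-9 or rgb.max() > 1 + 1e-9:
        raise ValueError("sRGB values must lie in [0, 1]")
    lab = _skcolor.rgb2lab(np.clip(rgb, 0.0, 1.0))
    return LabImage.from_stack(lab)


def lab_to_rgb(lab: LabImage) -> np.ndarray:
    """Inverse conversion; out-of-gamut sRGB values are clipped to [0, 1]."""
    arr = lab.stack() if isinstance(lab, LabImage) else np.asarray(lab)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # out-of-gamut values are expected from raw network outputs; the
        # clipping policy below handles them
        warnings.simplefilter("ignore", UserWarning)
        rgb = _skcolor.lab2rgb(arr)
    n_out = int(np.count_nonzero((rgb < 0) | (rgb > 1)))
    if n_out:
        logger.debug("lab_to_rgb clipped %d out-of-gamut values", n_out)
    return np.clip(rgb, 0.0, 1.0)


def normalize_lab(lab: LabImage) -> np.ndarray:
    """Affine map of a LabImage onto an H x W x 3 array in [-1, 1].

    L: [0,100] -> [-1,1]; a,b: [-128,127] -> [-1,1].
    """
    arr = lab.stack() if isinstance(lab, LabImage) else np.asarray(lab)
    out = np.empty_like(arr, dtype=np.float64)
    out[..., 0] = (arr[..., 0] - _L_SHIFT) / _L_SCALE
    out[..., 1:] = (arr[..., 1:] - _AB_SHIFT) / _AB_SCALE
    return out


def denormalize_lab(arr: np.ndarray) -> LabImage:
    """Inverse of :func:`normalize_lab`."""
    arr = np.asarray(arr, dtype=np.float64)
    lab = np.empty_like(arr)
    lab[..., 0] = arr[..., 0] * _L_SCALE + _L_SHIFT
    lab[..., 1:] = arr[..., 1:] * _AB_SCALE + _AB_SHIFT
    return LabImage.from_stack(lab)


def gray_to_normalized_lab(gray: np.ndarray) -> np.ndarray:
    """Embed a grayscale image in [0,1] as a normalized-Lab array.

    A gray pixel has zero chroma, so only L varies; this keeps single-channel
    B-mode inputs dimensionally compatible with 3-channel color outputs.  The
    opponent channels are set to exactly zero chroma rather than inheriting
    conversion round-off.
    """
    rgb = np.repeat(np.asarray(gray, dtype=np.float64)[..., None], 3, axis=-1)
    lab = rgb_to_lab(rgb)
    zero = np.zeros_like(lab.L)
    return normalize_lab(LabImage(lab.L, zero, zero))


def gaussian_blur(image: np.ndarray, kernel: GaussianKernel) -> np.ndarray:
    """Per-channel 2-D convolution with reflect padding (linear in input)."""
    image = np.asarray(image, dtype=np.float64)
    if abs(kernel.weights.sum() - 1.0) > 1e-9:
        raise ValueError("kernel must be normalized")
    if image.ndim == 2:
        return ndimage.convolve(image, kernel.weights, mode="reflect")
    out = np.empty_like(image)
    for c in range(image.shape[-1]):
        out[..., c] = ndimage.convolve(image[..., c], kernel.weights,
                                       mode="reflect")
    return out


def channel_entropy(images: list[np.ndarray], space: str = "rgb",
                    bins: int = 64) -> np.ndarray:
    """Shannon entropy (bits) per channel over the pooled pixels of a set.

    Histograms use `bins` equal-width bins over each channel's value range
    ([0,1] for sRGB; [0,100] and [-128,127] for Lab).  A concentrated
    distribution gives low entropy; elastograms are more concentrated in the
    opponent (a, b) channels than in R, G, B.
    """
    if not images:
        raise ValueError("need at least one image")
    if space == "rgb":
        ranges = [(0.0, 1.0)] * 3
        pooled = [np.asarray(im, dtype=np.float64).reshape(-1, 3)
                  for im in images]
    elif space == "lab":
        ranges = [(0.0, 100.0), (-128.0, 127.0), (-128.0, 127.0)]
        pooled = [rgb_to_lab(np.asarray(im)).stack().reshape(-1, 3)
                  for im in images]
    else:
        raise ValueError("space must be 'rgb' or 'lab'")
    px = np.concatenate(pooled, axis=0)
    out = np.empty(3)
    for c, (lo, hi) in enumerate(ranges):
        hist, _ = np.histogram(px[:, c], bins=bins, range=(lo, hi))
        p = hist / hist.sum()
        p = p[p > 0]
        out[c] = float(-(p * np.log2(p)).sum())
    return out
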