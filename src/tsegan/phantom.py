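"""Synthetic paired B-mode / elastogram phantoms with known stiffness scores.

Clinical strain-elastography pairs are not publicly available, so this module
generates seeded desk-scale stand-ins: a speckled grayscale background with a
darker elliptical "nodule" (the B-mode proxy) and a co-registered color
elastogram in which the fraction of blue-dominant pixels inside the nodule
encodes a 1-5 stiffness score (blue = stiff/inelastic, green = soft/elastic;
higher score = stiffer = more likely malignant).  Sparse red/yellow spots are
scattered over the soft background, mimicking the strain hot-spots real
elastograms show.

The phantom statistics (multiplicative Rayleigh speckle smoothed with a
sigma=2 px kernel, -0.3 luminance nodule contrast) are design choices of this
package, not measurements of clinical data.

Scores map to designed bands of the blue-dominant pixel fraction f:

    score 1: f in [0, 0.05]      (uniformly soft nodule)
    score 2: f in [0.15, 0.35]
    score 3: f in [0.40, 0.60]   (half blue, half green)
    score 4: f in [0.65, 0.85]
    score 5: f in [0.95, 1.0]    (uniformly stiff nodule)
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage, special
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "SCORE_BANDS", "PhantomConfig", "PairedSample", "generate_phantom_pair",
    "generate_dataset", "load_manifest", "blue_green_ratio", "extract_roi",
    "naive_segment", "score_from_ratio",
]

#: designed blue-dominant fraction band per stiffness score
SCORE_BANDS: dict[int, tuple[float, float]] = {
    1: (0.00, 0.05),
    2: (0.15, 0.35),
    3: (0.40, 0.60),
    4: (0.65, 0.85),
    5: (0.95, 1.00),
}

# sampling range inside each band: stay off the edges so that PNG
# quantization and pixel discretization cannot push a sample out of band
_SAMPLE_BANDS = {
    1: (0.010, 0.040),
    2: (0.180, 0.320),
    3: (0.430, 0.570),
    4: (0.680, 0.820),
    5: (0.960, 1.000),
}

# sRGB primaries of the phantom palette; dominance margins are large enough
# to survive 8-bit quantization and luminance modulation
_GREEN_BG = np.array([0.15, 0.62, 0.18])
_GREEN_NODULE = np.array([0.18, 0.58, 0.22])
_BLUE = np.array([0.10, 0.22, 0.72])
_RED_SPOT = np.array([0.72, 0.15, 0.10])
_YELLOW_SPOT = np.array([0.72, 0.68, 0.10])


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic pair."""

    image_size: int = 256
    nodule_radius_range: tuple[int, int] = (20, 60)
    target_score: int | str = "random"
    speckle_scale: float = 0.25
    spot_density: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64 (ROI pipeline needs room)")
        rmin, rmax = self.nodule_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("invalid nodule_radius_range")
        if self.image_size < 2 * rmax:
            raise ValueError("image_size must be >= 2 x max nodule radius")
        if self.target_score != "random" and self.target_score not in SCORE_BANDS:
            raise ValueError("target_score must be 1..5 or 'random'")
        if not 0.0 <= self.spot_density <= 1.0:
            raise ValueError("spot_density must lie in [0, 1]")
        if self.speckle_scale <= 0:
            raise ValueError("speckle_scale must be positive")


@dataclass
class PairedSample:
    """One aligned (B-mode, elastogram, mask, score) record."""

    bmode: np.ndarray       # H x W in [0, 1]
    elastogram: np.ndarray  # H x W x 3 sRGB in [0, 1]
    mask: np.ndarray        # H x W binary, nodule = 1
    score: int
    id: str

    def validate(self) -> "PairedSample":
        hw = self.bmode.shape
        if self.elastogram.shape[:2] != hw or self.mask.shape != hw:
            raise ValueError("bmode, elastogram and mask extents differ")
        n_comp = ndimage.label(self.mask > 0)[1]
        if n_comp != 1:
            raise ValueError(f"mask must have exactly 1 component, got {n_comp}")
        return self


def _ellipse_field(size: int, center: tuple[float, float],
                   radii: tuple[float, float], theta: float) -> np.ndarray:
    """Normalized squared elliptical distance (<=1 inside the nodule)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    c, s = np.cos(theta), np.sin(theta)
    u = c * dy + s * dx
    v = -s * dy + c * dx
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2


def generate_phantom_pair(config: PhantomConfig) -> PairedSample:
    """Generate one co-registered phantom pair, deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.image_size

    score = (int(rng.integers(1, 6)) if config.target_score == "random"
             else int(config.target_score))

    # nodule geometry: uniformly sampled interior center, random orientation
    rmin, rmax = config.nodule_radius_range
    radii = (float(rng.uniform(rmin, rmax)), float(rng.uniform(rmin, rmax)))
    theta = float(rng.uniform(0, np.pi))
    margin = max(radii) + 2.0
    center = (float(rng.uniform(margin, n - margin)),
              float(rng.uniform(margin, n - margin)))
    e = _ellipse_field(n, center, radii, theta)
    mask = (e <= 1.0).astype(np.uint8)
    soft_edge = special.expit(-(e - 1.0) / 0.05)  # ~2 px transition

    # B-mode: smooth background texture x multiplicative Rayleigh speckle.
    # Nodule contrast deepens with the stiffness score (mean -0.3), mirroring
    # the clinical association between hypoechogenicity and malignancy; this
    # is the cue that makes stiffness learnable from the grayscale input.
    background = 0.45 + 0.15 * ndimage.gaussian_filter(
        rng.standard_normal((n, n)), sigma=8.0)
    contrast = 0.30 + 0.07 * (score - 3)
    luminance = background - contrast * soft_edge
    speckle = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=(n, n))
    speckle = 1.0 + config.speckle_scale * (speckle - 1.0)
    bmode = np.clip(ndimage.gaussian_filter(luminance * speckle, sigma=2.0),
                    0.0, 1.0)

    # elastogram: green background, blue core of designed pixel fraction
    lo, hi = _SAMPLE_BANDS[score]
    f_target = float(rng.uniform(lo, hi))
    inside = e[mask.astype(bool)]
    k = int(round(f_target * inside.size))
    if k > 0:
        # threshold at the k-th smallest elliptical distance: the blue region
        # is a concentric inner set with exactly k pixels
        thresh = np.partition(inside, k - 1)[k - 1]
        blue_region = mask.astype(bool) & (e <= thresh)
    else:
        blue_region = np.zeros_like(mask, dtype=bool)

    elastogram = np.empty((n, n, 3))
    elastogram[:] = _GREEN_BG
    elastogram[mask.astype(bool)] = _GREEN_NODULE
    elastogram[blue_region] = _BLUE
    elastogram += 0.02 * ndimage.gaussian_filter(
        rng.standard_normal((n, n, 3)), sigma=(2.0, 2.0, 0.0))

    # sparse red/yellow strain spots on the soft background
    n_bg = int((mask == 0).sum())
    n_spots = rng.poisson(config.spot_density * n_bg / 20.0)
    for _ in range(n_spots):
        cy, cx = rng.uniform(0, n, size=2)
        if mask[int(cy) % n, int(cx) % n]:
            continue
        r_spot = rng.uniform(1.5, 3.5)
        col = _RED_SPOT if rng.random() < 0.5 else _YELLOW_SPOT
        d = _ellipse_field(n, (cy, cx), (r_spot, r_spot), 0.0)
        spot = (d <= 1.0) & (mask == 0)
        elastogram[spot] = col

    # luminance co-registration: modulate by the smoothed B-mode; a per-pixel
    # scalar factor preserves channel dominance
    lum = 0.85 + 0.3 * (ndimage.gaussian_filter(bmode, 3.0) - 0.4)
    elastogram = np.clip(elastogram * lum[..., None], 0.0, 1.0)

    sample = PairedSample(
        bmode=bmode, elastogram=elastogram, mask=mask, score=score,
        id=f"phantom-s{config.seed}-r{score}")
    return sample.validate()


def blue_green_ratio(elastogram: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of mask pixels whose blue channel strictly dominates.

    A pixel counts as blue when B > R and B > G; the complement inside a
    nodule is (in phantoms) green-dominant, so this is the programmatic
    stand-in for the clinical blue-to-green stiffness reading.
    """
    elastogram = np.asarray(elastogram)
    mask = np.asarray(mask).astype(bool)
    if elastogram.shape[:2] != mask.shape:
        raise ValueError("elastogram and mask extents differ")
    if not mask.any():
        raise ValueError("mask is empty")
    px = elastogram[mask]
    blue = (px[:, 2] > px[:, 0]) & (px[:, 2] > px[:, 1])
    return float(blue.mean())


def score_from_ratio(ratio: float) -> int:
    """Map a blue-dominant fraction to a 1-5 score by fixed band thresholds.

    Thresholds (0.05, 0.35, 0.60, 0.85) sit at the upper edges of the design
    bands; this is a programmatic proxy for human scoring, not a clinical
    instrument.
    """
    for score, upper in zip((1, 2, 3, 4), (0.05, 0.35, 0.60, 0.85)):
        if ratio <= upper:
            return score
    return 5


def extract_roi(image: np.ndarray, mask: np.ndarray,
                roi_size: int = 128) -> tuple[np.ndarray, tuple]:
    """Crop a roi_size x roi_size window centered on the mask centroid.

    The window is clamped to the image bounds (never padded), and returned as
    0-based half-open ((r0, r1), (c0, c1)) coordinates so the caller can
    place ROI-derived features back into the full frame.  An empty mask falls
    back to the image center with a logged warning.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    H, W = image.shape[:2]
    if H < roi_size or W < roi_size:
        raise ValueError(f"image smaller than roi_size={roi_size}")
    if mask.any():
        cy, cx = ndimage.center_of_mass(mask.astype(np.float64))
    else:
        logger.warning("empty mask: ROI falls back to the image center")
        cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    r0 = int(round(cy - roi_size / 2.0))
    c0 = int(round(cx - roi_size / 2.0))
    r0 = min(max(r0, 0), H - roi_size)
    c0 = min(max(c0, 0), W - roi_size)
    window = ((r0, r0 + roi_size), (c0, c0 + roi_size))
    crop = image[r0:r0 + roi_size, c0:c0 + roi_size]
    return crop, window


def naive_segment(bmode: np.ndarray) -> np.ndarray:
    """Coarse nodule segmentation: Otsu-threshold dark regions, keep the
    largest connected component, fill holes.

    A fallback for mask-free inference on arbitrary images only; phantom
    training uses the generator's exact masks.
    """
    bmode = np.asarray(bmode, dtype=np.float64)
    if bmode.max() == bmode.min():
        raise ValueError("constant image cannot be segmented")
    dark = bmode < threshold_otsu(bmode)
    labels, n = ndimage.label(dark)
    if n == 0:
        raise ValueError("no dark region found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    largest = (labels == (1 + int(np.argmax(sizes))))
    return ndimage.binary_fill_holes(largest).astype(np.uint8)


# -- dataset I/O ------------------------------------------------------------

def _save_png(path: Path, arr: np.ndarray) -> None:
    arr8 = np.clip(np.round(np.asarray(arr, dtype=np.float64) * 255.0),
                   0, 255).astype(np.uint8)
    Image.fromarray(arr8).save(path)


def generate_dataset(n: int, config: PhantomConfig, out_dir: str | Path) -> Path:
    """Write n phantom pairs as PNG triplets plus a TSV manifest.

    Sample i uses seed ``config.seed + i``.  With target_score="random",
    scores are balanced 1..5 in a seeded random order.  Returns the manifest
    path.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    if config.target_score == "random":
        scores = [1 + i % 5 for i in range(n)]
        rng.shuffle(scores)
    else:
        scores = [int(config.target_score)] * n

    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("id\tbmode_path\tse_path\tmask_path\tscore\n")
        for i in range(n):
            cfg = replace(config, seed=config.seed + i, target_score=scores[i])
            sample = generate_phantom_pair(cfg)
            sid = f"{i:04d}-{sample.id}"
            names = (f"{sid}_bmode.png", f"{sid}_se.png", f"{sid}_mask.png")
            _save_png(out_dir / names[0], sample.bmode)
            _save_png(out_dir / names[1], sample.elastogram)
            _save_png(out_dir / names[2], sample.mask.astype(np.float64))
            fh.write(f"{sid}\t{names[0]}\t{names[1]}\t{names[2]}\t"
                     f"{sample.score}\n")
    return manifest


def load_manifest(manifest: str | Path) -> list[PairedSample]:
    """Read a TSV manifest back into memory; corrupt rows are skipped."""
    manifest = Path(manifest)
    root = manifest.parent
    samples: list[PairedSample] = []
    with open(manifest) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError("not a phantom manifest")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                logger.warning("skipping corrupt manifest row: %r", line)
                continue
            sid, bpath, spath, mpath, score = parts
            try:
                bmode = np.asarray(Image.open(root / bpath),
                                   dtype=np.float64) / 255.0
                se = np.asarray(Image.open(root / spath),
                                dtype=np.float64) / 255.0
                mask = (np.asarray(Image.open(root / mpath)) > 127
                        ).astype(np.uint8)
                samples.append(PairedSample(bmode, se, mask, int(score), sid))
            except (OSError, ValueError) as err:
                logger.warning("skipping unreadable row %s: %s", sid, err)
    if not samples:
        raise ValueError("no usable samples in manifest")
    return samples


def manifest_checksum(manifest: str | Path) -> str:
    """SHA-256 over the manifest and every file it references."""
    manifest = Path(manifest)
    h = hashlib.sha256(manifest.read_bytes())
    root = manifest.parent
    with open(manifest) as fh:
        fh.readline()
        for line in fh:
            for rel in line.rstrip("\n").split("\t")[1:4]:
                h.update((root / rel).read_bytes())
    return h.hexdigest()
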