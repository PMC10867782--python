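# Methods

## Problem and model

The package learns a mapping from grayscale B-mode thyroid ultrasound to the
color strain elastogram (SE) a compression exam would produce. The mapping
is a conditional GAN with a global-to-local generator: a full-frame branch
captures anatomy-scale context while a dedicated branch translates the
128×128 nodule region of interest (ROI), where stiffness contrast matters
clinically. Three design elements address failure modes of generic
image-to-image translation on this task:

* **Deformable convolutions in the ROI encoder.** Thyroid tissue deforms
  non-rigidly under probe compression; fixed square receptive fields model
  this poorly. Each encoder convolution therefore samples its input at
  kernel-tap positions displaced by a learned offset field (bilinear
  interpolation, zeros outside bounds). Offset-prediction layers are
  zero-initialised so optimisation starts exactly at the plain-convolution
  special case; this reduction is asserted in the tests.
* **SPADE decoding in the ROI branch.** Instance normalization in decoders
  causes boundary artifacts; instead the decoder standardizes each channel
  (parameter-free, per sample) and modulates it with γ/β maps predicted from
  the concatenated encoder skip features and the raw ROI, re-injecting
  spatial detail that normalization removes.
* **Content revisor output head.** The global decoder features are split
  into n−1 = 4−1 foreground content masks (tanh-bounded) plus the raw input
  as background; a channel-attention head (global average + max pooling
  through a shared fully-connected layer, softmax over the n groups) weights
  them. The output is a convex combination, so it stays in [−1, 1] and
  degenerates to the unmodified input when the background weight saturates —
  both are tested invariants.

Two PatchGAN discriminators with identical architecture but independent
parameters judge full-frame and ROI pairs conditioned on the source image.
Their intermediate stage features feed the feature-matching loss. The
discriminator depth is capped so that the final logit stage keeps at least a
2-pixel extent (4 strided stages at 128-pixel ROIs, fewer at the reduced
desk sizes).

## Color representation and losses

Elastogram semantics are chromatic: blue = stiff, green = soft. All network
arithmetic happens in CIELAB (D65/2°, the sRGB convention), affinely
normalized per channel to [−1, 1] (L: [0,100]; a, b: [−128,127]). Grayscale
inputs embed with exactly zero chroma. The objective is

L = Σₖ L_GAN(G,Dₖ) + α Σₖ L_FM(G,Dₖ) + β L_color, α = 10, β = 0.001.

* Adversarial terms are binary cross-entropy on raw patch logits, computed
  via softplus (log-sum-exp) for overflow safety; the generator uses the
  non-saturating variant. The ROI and full-frame adversarial terms enter
  unweighted, mirroring the symmetric sum over discriminators.
* Feature matching sums per-stage L1 distances scaled by 1/Nᵢ (element count
  of stage i); real-pair features are treated as constants during the
  generator update.
* The color loss blurs both images with a normalized Gaussian kernel
  (default 21×21, σ = 3 at 256² resolution — large enough to suppress
  texture while keeping color composition; 9×9 in the desk profile for
  64-pixel crops) and sums squared plus absolute differences over all
  elements. Sums, not means: the small β is calibrated to that scale. The
  kernel uses reflect padding, so constants are fixed points. A variant that
  interposes an extra learned convolution before the distance was
  considered and rejected: the distance formula is complete without it, and
  a learned distance would no longer be a fixed training signal.

## Training recipe

Adam with two time scales (generator 2·10⁻⁴, discriminators 10⁻⁴,
β₁ = 0.5, β₂ = 0.999), one discriminator update per generator update,
discriminators first on detached fakes. Xavier initialisation everywhere
except the zero-initialised offset heads. Augmentation applies, per pair and
with one shared parameter draw: horizontal/vertical mirrors, rotations
within ±15°, simultaneous horizontal+vertical ("diagonal") translations
within ±20 px — each independently with probability 0.5 — followed by a
resize to crop_size + 32 and a random crop to crop_size (center crop when
augmentation is disabled). The +32 margin is a package choice; nothing
deeper than "leave room for a non-trivial crop". All randomness flows from
one seeded numpy Generator whose state is checkpointed, so a resumed run
reproduces an uninterrupted one bit for bit on one CPU.

The networks run on `tsegan.nn`, a compact float64 reverse-mode autodiff
core written for this package (Tensor graph, im2col convolutions,
transposed/depthwise/deformable convolutions, batch normalization, Adam).
Every nontrivial primitive's gradient is pinned against central finite
differences, and convolution forwards against scipy oracles.

## Synthetic phantoms

Clinical SE pairs are not available, so the `phantom` module generates the
study data: a smoothed random background (≈0.45 mean luminance) with an
elliptical nodule (radii drawn from a configurable band, uniformly placed
interior center, random orientation), multiplied by smoothed multiplicative
Rayleigh speckle (σ = 2 px kernel). The paired elastogram is green-dominant
with a concentric blue core whose pixel fraction f encodes the 1–5
stiffness score through fixed design bands (score 1: f ≤ 0.05 … score 5:
f ≥ 0.95); the core is cut at an exact quantile of the elliptical distance,
so the realized fraction lands in-band deterministically. Sparse red/yellow
spots dot the soft background, and a per-pixel luminance factor derived
from the smoothed B-mode co-registers the two images without disturbing
channel dominance. Nodule contrast deepens with score
(−0.30 − 0.07·(score−3), mean −0.3): hypoechogenicity correlates with
malignancy clinically, and it is the cue that makes stiffness recoverable
from the grayscale input at all. The scorer proxy `blue_green_ratio` counts
strictly blue-dominant pixels (B > R and B > G) inside the mask; hue-angle
classification was rejected as needlessly parametric.

What the phantoms do **not** emulate: acoustic wave physics, realistic
speckle statistics of tissue, calcifications, cystic components, multiple
nodules, probe-pressure variability, or inter-observer scoring noise.
Passing tests therefore demonstrate that the architecture, losses and
training loop function and that the stiffness cue is learnable — not
clinical performance. Masks are generator ground truth during training; the
Otsu-based `naive_segment` (threshold dark regions, keep largest component,
fill holes) exists only for mask-free inference and is documented as coarse
(IoU ≥ 0.3 against true phantom masks).

## Evaluation

PSNR, SSIM and MSE are computed on 8-bit sRGB renderings (dynamic range
255), the domain of clinical screenshots. PSNR of identical images is
reported as a 100 dB sentinel. SSIM ships in two modes: "global" evaluates
the formula once with whole-image moments; "windowed" (default, the
community convention) averages over 11×11 Gaussian windows (σ = 1.5) and is
cross-checked against scikit-image. MSE is the plain per-element mean
(channels included), which closes the PSNR = 10·log₁₀(255²/MSE) identity
exactly. Human stiffness scoring is replaced by the blue/green-ratio proxy
with fixed band thresholds (≤0.05 → 1, ≤0.35 → 2, ≤0.60 → 3, ≤0.85 → 4,
else 5) — a programmatic stand-in, not a clinical instrument.

## Desk-scale reference study

The reference experiment (`tsegan.desk`) sizes everything for one CPU:
32 training phantoms rendered at 96 px and cropped to 64 px, 8 base
channels (≈4.3·10⁵ generator parameters), ROI 32 px, batch 4, 200 Adam
steps; held-out sets of 8 phantoms (image fidelity) and 50 phantoms
(10 per score, stiffness recovery) are generated from disjoint seed
offsets. Reported outcomes: the median total generator loss over the first
versus last 10% of steps, trained-versus-initialised held-out PSNR, and the
Spearman correlation between true scores and generated blue/green ratios.
`scripts/acceptance.py` reruns the whole study from scratch under a given
seed and writes these quantities as JSON.

## Known limitations

* Desk-scale training (200 steps, 64 px) demonstrates optimisation and cue
  recovery, not converged image quality; SSIM in particular stays low.
* The autodiff core is single-threaded numpy: full-size (256 px, 64-channel)
  training is functional but slow; the architecture is configured for it,
  not benchmarked at it.
* Attention in the content revisor is per-channel-scalar (pooled), not
  per-pixel; a spatial-softmax variant is a plausible alternative reading of
  the design and was not implemented.
* The local-to-global fusion injects pooled ROI features only inside the
  scaled ROI window (zeros elsewhere); a global broadcast would discard
  registration and was rejected.
* Checkpoints are Python pickles; they are trusted inputs, not an exchange
  format.
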