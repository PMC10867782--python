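# tsegan

Conditional-GAN translation of grayscale B-mode thyroid ultrasound frames
into color strain elastograms, for researchers studying learned surrogates
of compression elastography.

Strain elastography (SE) renders tissue stiffness as a color overlay —
blue for stiff (sclerotic, more likely malignant) tissue, green for soft
elastic tissue — but depends on a hand-compression protocol that is hard to
standardize. `tsegan` learns the B-mode → SE mapping from aligned image
pairs, so a stiffness rendering can be synthesized from the conventional
grayscale exam alone. Because clinical SE pairs are rarely shareable, the
package also ships a seeded synthetic **phantom** generator that produces
co-registered (B-mode, elastogram, nodule mask, stiffness score) records,
making the whole pipeline trainable and testable on one CPU.

## Model

The generator G has three cooperating parts:

* **Local generator** `G_local` on the 128×128 nodule region of interest: an
  encoder of deformable-convolution residual blocks (7×7 first kernel, 3×3
  afterwards) whose sampling taps follow learned per-position offsets, nine
  residual fusion blocks, and a decoder of SPADE (spatially-adaptive
  denormalization) residual blocks conditioned on encoder skips and the raw
  ROI.
* **Global generator** `G_global` on the 256×256 frame: a spatial-attention
  encoder whose bottleneck receives the local decoder features summed into
  the (scaled) ROI window, nine residual blocks, and a transposed-convolution
  decoder.
* **Content revisor**: from the decoder features m it derives n−1 = 3
  foreground content masks C_f = tanh(conv_f(m)) and an n-way channel
  attention A = softmax(FC(AP(A_mid)) + FC(MP(A_mid))); the output is
  Σ_f C_f·A_f + x·A_n, so the background of the input x is preserved exactly
  when its attention weight saturates.

Two conditional PatchGAN discriminators D₁ (full frame) and D₂ (ROI) judge
(source, target) channel concatenations. All images are encoded as CIELAB
values affinely normalized to [−1, 1] — the opponent a/b axes isolate the
blue↔green stiffness signal — and the objective is

    L = Σₖ L_GAN(G, Dₖ) + α Σₖ L_FM(G, Dₖ) + β L_color(G),  α = 10, β = 0.001

with binary-cross-entropy adversarial terms, discriminator feature matching
(per-stage L1, scaled by 1/Nᵢ), and a color loss ‖X_b−Y_b‖₂² + ‖X_b−Y_b‖₁ on
Gaussian-blurred images. Training uses Adam with two time scales
(generator 2·10⁻⁴, discriminators 10⁻⁴, β₁ = 0.5, β₂ = 0.999), Xavier
initialisation, and paired geometric augmentation (±20 px translations,
±15° rotations, mirror flips, each with probability 0.5).

Networks run on a small numpy reverse-mode autodiff core (`tsegan.nn`) with
exact gradients for standard, transposed, depthwise and deformable
convolutions, verified against finite differences in the test suite.

## Worked example

Generate a phantom dataset, train the desk-scale profile, evaluate:

```
tsegan simulate --n 32 --size 96 --seed 42 --out data/train
tsegan train --manifest data/train/manifest.tsv --out runs/desk --seed 42 \
    --set train.batch_size=4 --set train.crop_size=64 \
    --set train.max_steps=200 --set train.blur_size=9 \
    --set net.base_channels=8 --set net.roi_size=32 --set net.global_size=64
tsegan evaluate --checkpoint runs/desk/checkpoint_final.pkl \
    --manifest data/train/manifest.tsv --out runs/desk/report.csv
```

A single phantom pair carries its stiffness ground truth; for example

```python
>>> from tsegan.phantom import PhantomConfig, generate_phantom_pair, blue_green_ratio
>>> s = generate_phantom_pair(PhantomConfig(image_size=96,
...     nodule_radius_range=(10, 24), seed=7, target_score=4))
>>> round(blue_green_ratio(s.elastogram, s.mask), 3)
0.778
```

— 77.8% of the nodule's pixels are blue-dominant, inside the designed
[0.65, 0.85] band for score 4 (blue overall with a little green). During
training the CSV loss log records every objective component; the first line
of a seed-42 desk run reads

```
iteration,adv_d1,adv_d2,adv_g,fm_d1,fm_d2,color,total_g
1,0.8831146449,0.7572213904,1.38241352,1.09583917,1.538306558,15783.80871,43.50767951
```

i.e. total_g = adv_g + 10·(fm_d1+fm_d2) + 0.001·color. Over 200 steps the
median total generator loss falls from ≈32 to ≈15, the trained checkpoint's
held-out PSNR rises to ≈15.1 dB versus ≈11.7 dB at initialisation, and the
Spearman correlation between true phantom scores and the blue/green ratio of
the generated elastograms reaches ≈0.97.

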