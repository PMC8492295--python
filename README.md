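# cgdenoise

Conditional-GAN denoising for grayscale medical-style images (chest
radiographs, CT slices) corrupted by mixed, unknown noise — Gaussian,
salt-and-pepper, or both at once.  The package is aimed at researchers who
want a small, fully deterministic, CPU-only reference implementation of
gradient-conditioned adversarial denoising that can be trained, ablated and
evaluated end to end on built-in synthetic phantoms, with no external
dataset or GPU.

## Method

Given a noisy image *x* and its clean counterpart *y*, a generator *G* with
residual dense blocks (RDBs) learns the mapping *x → y* inside a conditional
Wasserstein GAN:

- **Gradient enhancement (conditioning).**  Per-pixel forward differences
  gx(i,j) = f(i, j+1) − f(i, j), gy(i,j) = f(i+1, j) − f(i, j) give the
  magnitude map M = √(gx² + gy²).  Isolated noise impulses produce stronger
  gradients than anatomy, so all magnitudes at or below the median of M are
  zeroed and the surviving strong gradients are added back onto *x*.  The
  stack [enhanced, raw noisy] conditions the generator; the critic scores
  pairs {enhanced, clean} vs {enhanced, G(x)}.
- **Generator.**  4 outer convolutions (instance norm + Leaky ReLU) around a
  chain of 6 RDBs.  Inside an RDB, layer *n* receives the concatenation
  [F_{d−1}, F_{d,1}, …, F_{d,n−1}] of the block input and all earlier layer
  outputs, a 1×1 convolution fuses the stack, and a residual addition closes
  the block.  The network is fully convolutional: train on 70×70 crops,
  denoise full 256×256 images with the same weights.
- **Objective.**  L_total = L_W-GAN + λ₁·L_Recon with λ₁ = 0.5, where
  L_Recon = mean |y − G(x)| (L1 preserves structure; L2 blurs) and the
  critic maximizes E[D(real)] − E[D(fake)] under a 1-Lipschitz constraint
  (weight clipping at 0.01 by default, gradient penalty optional).
- **Evaluation.**  PSNR = 10·log₁₀((2ⁿ−1)²/MSE) on the n-bit scale
  (n = 8 by default), windowed SSIM, and min-max-normalized absolute
  residual maps.

All tensor computation runs on a small reverse-mode numpy layer library
shipped with the package (`cgdenoise.nn`); every backward pass is verified
against finite differences in the test suite.

## Worked example

```python
import numpy as np
from cgdenoise import (NoiseSpec, make_phantom, add_noise,
                       compute_gradient_map, threshold_gradient_map, psnr, ssim)
from cgdenoise.benchmark import run_smoke

clean = make_phantom(64, 64, complexity=3, seed=7)
noisy = add_noise(clean, NoiseSpec("gaussian", sigma=0.15, seed=3))
gmap = threshold_gradient_map(compute_gradient_map(noisy))
print(f"noisy PSNR = {psnr(clean, noisy):.2f} dB, SSIM = {ssim(clean, noisy):.3f}")
print(f"gradient median threshold = {gmap.threshold_value:.4f}")

result = run_smoke(seed=0, steps=200)   # 8 train / 4 held-out phantoms, 32x32
print(f"held-out PSNR: noisy {result['psnr_noisy_db']:.2f} dB -> "
      f"denoised {result['psnr_denoised_db']:.2f} dB")
```

prints

```
noisy PSNR = 17.20 dB, SSIM = 0.279
gradient median threshold = 0.2273
held-out PSNR: noisy 17.32 dB -> denoised 21.41 dB
```

The first two lines quantify the corruption (a σ = 0.15 Gaussian pushes the
phantom to ~17 dB, the badly-degraded regime) and the conditioning step (half
of all pixels survive the median threshold, by construction).  The smoke run
then trains the full adversarial pipeline for 200 steps on CPU and gains
about 4 dB over the noisy input on phantoms it never saw, with SSIM rising
from 0.554 to 0.729.

The same workflows are available from the shell:

```sh
cgdenoise synth --n-pairs 8 --size 256 --noise gaussian:0.18 --seed 0 --out-dir data/
cgdenoise enhance --in data/noisy_0000.png --out enhanced.png --save-gradient gmap.png
cgdenoise train --data-manifest data/manifest.json --epochs 25 --out-dir run/ --seed 0
cgdenoise denoise --checkpoint run/checkpoint.npz --in data/noisy_0000.png --out denoised.png
cgdenoise evaluate --pairs pairs.json --out metrics.csv --residual-dir residuals/
cgdenoise ablate --out-dir ablation/ --seed 0
```

## Layout

- `cgdenoise.synthetic` — phantom generator, noise models, paired datasets
- `cgdenoise.gradients` — gradient maps, median thresholding, enhancement
- `cgdenoise.nn` / `cgdenoise.networks` — layer library; generator and critic
- `cgdenoise.losses` — L1 + Wasserstein objective, Lipschitz enforcement
- `cgdenoise.training` — patch cropping, train loop, checkpoints, inference
- `cgdenoise.evaluation` — PSNR, SSIM, residual maps, comparison tables
- `cgdenoise.benchmark` — smoke benchmark and ablation harness

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
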