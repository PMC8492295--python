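# Methods

## Problem model

A corrupted observation x of a clean image y is produced by additive
Gaussian noise, salt-and-pepper impulses, or their composition; the noise
family and severity are treated as unknown at denoising time.  The denoiser
is a conditional generative adversarial pair: a generator G maps a
conditioning stack derived from x to an estimate of y, and a Wasserstein
critic D scores conditioned pairs, pushing the distribution of G's outputs
toward the distribution of clean images given the same conditioning.

Images are 2-D float arrays on the canonical [0, 1] intensity scale and at
least 2x2 (the forward-difference operators need one neighbor).  All
clipping saturates, never wraps, mirroring detector saturation.

## Gradient-enhanced conditioning

An isolated impulse differs from every neighbor, so its forward-difference
gradient magnitude M = sqrt(gx^2 + gy^2) is large and spatially incoherent,
while anatomy produces weaker or coherent gradients.  The conditioning step
zeroes all magnitudes at or below the median of M and adds the survivors
back onto the noisy image, amplifying noise evidence for both networks.

Numerical choices:

- The forward difference at the last column/row uses replicate padding
  (difference with the clamped neighbor, identically zero), keeping output
  dimensions equal to input dimensions with no spurious edge response.
- The median is taken over all H*W magnitudes including zeros; even counts
  use the standard midpoint.
- The comparison direction is a deliberate design choice.  Reading the
  thresholding rule as "keep what is below the median" would retain the
  weak, structure-scale gradients, which contradicts the physical rationale
  that impulses carry the *strong* gradients; this implementation therefore
  keeps strictly-above-median magnitudes by default.  The opposite reading
  remains available (`threshold_gradient_map(..., keep="below")`) for
  comparison.
- Gradient magnitudes are added in intensity units with scale 1 (no
  renormalization), then clipped.

The generator conditions on the 2-channel stack [enhanced, raw noisy] so
un-enhanced evidence is preserved; a 1-channel variant (noisy only) is the
gradient-enhancement ablation.  The critic conditions on the enhanced image
alone and scores it against either the clean image or the generator output.

## Architecture

Generator: 4 outer convolutions (3x3) and 6 residual dense blocks at a
fixed width.  The outer convolutions are 1 head, 2 tail-fusion and 1 output
projection; head and tails carry instance normalization and Leaky ReLU
(slope 0.2), and the projection is squashed into [0, 1] by a logistic map
so the output always satisfies the intensity invariant.  Inside an RDB,
internal layer n convolves the concatenation of the block input and all
earlier internal outputs (dense connectivity), a 1x1 convolution fuses the
stack back to the block width, and a local residual addition closes the
block; internals use plain ReLU and no normalization, which is known to
degrade restoration quality inside dense blocks.  Defaults: 64 block
channels, 3 internal layers, growth 32 — a small faithful instantiation of
the residual-dense design.  A block with zeroed fusion weights is an exact
identity, which both tests and the RDB ablation exploit.

Critic: 4 strided 3x3 convolutions doubling channels from 64 (instance
normalization on all but the first stage, Leaky ReLU 0.2), then a fully
connected layer to a single unbounded score — a scalar Wasserstein critic,
not a patch map, and no sigmoid.  The fully connected head fixes the
critic's input size to the training patch size; the generator itself is
fully convolutional and infers at any size above a 16-pixel floor.

## Objective and optimization

total_G = wgan_g + lambda1 * recon, with recon the mean absolute pixel
difference (the L1 norm is normalized per pixel so lambda1 = 0.5 keeps the
same meaning at 70x70 training crops and 256x256 inference) and
wgan_g = -E[D(fake pair)].  The critic maximizes
E[D(real)] - E[D(fake)].  Each step runs the critic update first (standard
practice for Wasserstein critics), then the generator update; the critic
update ratio defaults to 1, matching the alternating single-pair scheme.

Lipschitz enforcement defaults to weight clipping at 0.01, the original
Wasserstein-critic mechanism.  A gradient-penalty mode is provided: the
penalty value coef * mean((||grad_x D(x_hat)|| - 1)^2) over chord-sampled
interpolates is computed exactly from first-order input gradients, but its
exact parameter gradient requires double backpropagation, which the layer
library does not implement; in training, gradient-penalty mode therefore
penalizes the finite-difference Lipschitz quotient
|D(real) - D(fake)| / ||real - fake|| above 1 along the real-fake chord,
a first-order surrogate of the same constraint.  Clipping remains the
default and is exact.

Optimization uses Adam with betas (0.5, 0.9) — low first-moment momentum is
customary for adversarial critics — learning rate 2e-3, batch size 1, and
one random 70x70 crop per image per epoch, with the same offset applied to
clean, noisy and enhanced channels.  Convolution weights initialize from
N(0, 0.02^2).  The epoch count has no default: it is a required
configuration value.

Determinism: parameter initialization, dataset order and crop offsets all
derive from a single seed sequence; a checkpoint stores parameters, Adam
moments, the loss history and the full random-stream state, so a resumed
run reproduces the uninterrupted trajectory bit for bit.

## Synthetic data

The phantom generator emulates the gross second-order statistics of a
projection radiograph: a Gaussian-smoothed random background (low-frequency
shading), 1 or more bright ellipses with hard boundaries (nodule and
mediastinum analogues) and one sinusoidal ribbon (a rib analogue)
contributing long sharp edges, contrast-stretched so the pixel standard
deviation is well above 0.05.  Noise models: additive Gaussian (sigma in
intensity units), salt-and-pepper (independent per-pixel saturation to 1 or
0), and their composition as the "mixed/unknown" regime.  The default
severity preset (sigma 0.18, p_salt = p_pepper = 0.02) is a tuning constant
of this package chosen to land noisy-vs-clean PSNR in the 15-18 dB range of
a badly corrupted radiograph.

What passing tests on phantoms do *not* show: anatomical realism (true rib
cages, vasculature, texture spectra), spatially varying or correlated
noise, scanner-specific artifacts.  Results on phantoms demonstrate that
the pipeline's mechanics work and that the conditioning and adversarial
components behave as designed — not clinical performance.

## Evaluation

PSNR rescales [0, 1] images by 2^n - 1 (n = 8 default; the 15-35 dB range
of interest presumes an 8-bit dynamic range) before the mean squared
error; identical images report an infinite sentinel.  SSIM uses the
standard 11x11 Gaussian-weighted window (sigma 1.5, k1 = 0.01, k2 = 0.03)
averaged over the image, computed by scikit-image; a "global" mode
evaluates the single-window statistic with sample (n-1) moments and serves
as the closed-form oracle in tests.  The stabilizers are C1 = (k1 L)^2,
C2 = (k2 L)^2 with L the dynamic range.  Residual images are
|reference - denoised| min-max normalized to [0, 1] (all zeros when the
difference is constant); the reference defaults to the ground truth, with
the noisy-reference variant exposed as an option.

## Benchmark scale

The smoke benchmark trains on 8 phantoms (32x32, Gaussian sigma 0.15) for
200 steps and evaluates on 4 held-out phantoms, using a narrow network
(16 base channels, growth 8, 6 blocks, 3-stage critic) so a full run takes
seconds on one CPU while preserving every structural element of the
method.  On this problem the denoiser gains roughly 4 dB PSNR over the
noisy input; the ablation harness repeats the run without RDBs, without
gradient enhancement, and with the L1-only objective, and tabulates mean
PSNR/SSIM per variant next to the noisy baseline.

## Implementation notes

No deep-learning framework is used: `cgdenoise.nn` is a small reverse-mode
layer library (convolution as a kernel-offset sum of channel contractions,
instance normalization, Leaky ReLU, linear, Adam) operating on float64
``(N, C, H, W)`` arrays.  Convolution column matrices are never
materialized, keeping full-resolution inference within ~2 GB.  All
backward passes are validated against central finite differences in the
test suite.

## Known limitations

- The critic's fully connected head ties it to one patch size; multi-scale
  or patch critics are out of scope.
- Exact gradient-penalty training would need double backpropagation (see
  above); weight clipping is the supported default.
- 3-D volumes, DICOM ingestion, perceptual (VGG) losses and learning-rate
  schedules are out of scope.
- CPU-only float64 compute: full 256x256 inference with the default widths
  takes tens of seconds; training at realistic scale is not the goal of
  this implementation.
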