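"""Hybrid objective: L1 reconstruction + conditional Wasserstein adversarial loss.

The generator minimizes ``total_g = wgan_g + lambda1 * recon`` where
``recon`` is the mean absolute pixel difference between the ground truth
and the generator output (L1 preserves structure; L2 regresses to the
mean and blurs), and ``wgan_g = -E[D(fake pair)]``.  The critic maximizes
``E[D(real pair)] - E[D(fake pair)]``, the empirical Wasserstein-1
surrogate, under a 1-Lipschitz constraint enforced by weight clipping
(default) or a gradient penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import check_same_shape


@dataclass(frozen=True)
class LossWeights:
    """lambda1 weights the reconstruction term of the generator objective."""

    lambda1: float = 0.5

    def __post_init__(self) -> None:
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be >= 0")


@dataclass(frozen=True)
class LossReport:
    recon: float
    wgan_g: float
    wgan_d: float
    total_g: float


def reconstruction_loss(raw: np.ndarray, denoised: np.ndarray) -> float:
    """Mean absolute per-pixel difference; 0 iff the images are identical."""
    raw = np.asarray(raw, dtype=np.float64)
    denoised = np.asarray(denoised, dtype=np.float64)
    check_same_shape(raw, denoised)
    return float(np.mean(np.abs(raw - denoised)))


def reconstruction_loss_grad(raw: np.ndarray, denoised: np.ndarray) -> np.ndarray:
    """d(reconstruction_loss)/d(denoised): sign(denoised - raw) / n_pixels."""
    check_same_shape(raw, denoised)
    return np.sign(denoised - raw) / denoised.size


def critic_objective(score_real, score_fake) -> float:
    """mean(score_real) - mean(score_fake); the critic ascends this."""
    score_real = np.atleast_1d(np.asarray(score_real, dtype=np.float64))
    score_fake = np.atleast_1d(np.asarray(score_fake, dtype=np.float64))
    if score_real.size == 0 or score_fake.size == 0:
        raise ValueError("score batches must be non-empty")
    return float(score_real.mean() - score_fake.mean())


def generator_adversarial(score_fake) -> float:
    """-mean(score_fake): the generator maximizes the critic's score of fakes."""
    score_fake = np.atleast_1d(np.asarray(score_fake, dtype=np.float64))
    if score_fake.size == 0:
        raise ValueError("score batch must be non-empty")
    return float(-score_fake.mean())


def total_generator_loss(wgan_g: float, recon: float, weights: LossWeights) -> float:
    if recon < 0:
        raise ValueError("reconstruction loss must be >= 0")
    return wgan_g + weights.lambda1 * recon


def clip_weights(module, bound: float) -> None:
    """Clamp every parameter of ``module`` into [-bound, bound] in place."""
    if bound <= 0:
        raise ValueError("clip bound must be > 0")
    for _, layer, p in module.param_items():
        np.clip(layer.params[p], -bound, bound, out=layer.params[p])


def gradient_penalty(
    critic,
    conditioning: np.ndarray,
    real: np.ndarray,
    fake: np.ndarray,
    coefficient: float,
    rng: np.random.Generator,
) -> float:
    """coefficient * mean((||grad_x D(x_hat)||_2 - 1)^2) over interpolated pairs.

    ``x_hat`` interpolates the candidate channel between real and fake at a
    uniform random weight per sample; the gradient is taken with respect to
    the full stacked critic input.  ``critic`` must expose
    ``input_gradient(x)`` returning per-sample input gradients.
    """
    if coefficient <= 0:
        raise ValueError("gradient-penalty coefficient must be > 0")
    eps = rng.random((real.shape[0],) + (1,) * (real.ndim - 1))
    x_hat = np.concatenate([conditioning, eps * real + (1.0 - eps) * fake], axis=1)
    g = critic.input_gradient(x_hat)
    norms = np.sqrt(np.sum(g * g, axis=tuple(range(1, g.ndim))))
    return float(coefficient * np.mean((norms - 1.0) ** 2))


def enforce_lipschitz(critic, mode: str, bound_or_coef: float, **kwargs):
    """Apply the configured Lipschitz mechanism to a Wasserstein critic.

    ``mode="clip"`` clamps every critic parameter into
    [-bound_or_coef, +bound_or_coef] and returns the critic.
    ``mode="gradient_penalty"`` returns the penalty value (pass
    ``conditioning``, ``real``, ``fake`` and ``rng`` as keyword
    arguments).
    """
    if mode == "clip":
        clip_weights(critic, bound_or_coef)
        return critic
    if mode == "gradient_penalty":
        return gradient_penalty(
            critic,
            kwargs["conditioning"],
            kwargs["real"],
            kwargs["fake"],
            bound_or_coef,
            kwargs["rng"],
        )
    raise ValueError("mode must be 'clip' or 'gradient_penalty'")
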