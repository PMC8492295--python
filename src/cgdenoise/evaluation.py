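"""PSNR, SSIM and residual-map evaluation of denoising results.

PSNR is computed on the n-bit integer scale: [0, 1] float images are
multiplied by ``2**n_bits - 1`` (default 8 bits, peak 255) before the
mean squared error, so values land in the familiar 15-35 dB range for
natural dynamic ranges.  SSIM uses the standard 11x11 Gaussian-weighted
sliding window (sigma 1.5, k1=0.01, k2=0.03) averaged over the image via
scikit-image; ``mode="global"`` instead evaluates the single-window
statistic over the whole image with sample (n-1) moments, useful as a
closed-form cross-check.

Residual images are min-max-normalized absolute differences: bright
pixels flag places where the denoiser changed structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .image import check_same_shape, validate_image

SSIM_K1 = 0.01
SSIM_K2 = 0.03


@dataclass
class MetricReport:
    psnr: float  # decibels; math.inf when the pair is identical
    ssim: float
    n_bits: int
    per_image: list[tuple[str, float, float]] | None = None

    def to_frame(self) -> pd.DataFrame:
        """Per-image rows plus a summary row of means (Table-style layout)."""
        rows = list(self.per_image or [])
        rows.append(("mean", self.psnr, self.ssim))
        return pd.DataFrame(rows, columns=["id", "psnr_db", "ssim"])


@dataclass
class ResidualImage:
    values: np.ndarray
    reference_kind: str = "ground_truth"


def psnr(reference: np.ndarray, test: np.ndarray, n_bits: int = 8) -> float:
    """10*log10(peak^2 / MSE) with peak = 2**n_bits - 1; inf for identical images."""
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    ref = validate_image(reference, "reference")
    tst = validate_image(test, "test")
    check_same_shape(ref, tst)
    peak = float(2**n_bits - 1)
    mse = float(np.mean((peak * (ref - tst)) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def ssim(patch1: np.ndarray, patch2: np.ndarray, mode: str = "windowed") -> float:
    """Structural similarity in [-1, 1]; exactly 1 iff the patches are identical."""
    a = validate_image(patch1, "patch1")
    b = validate_image(patch2, "patch2")
    check_same_shape(a, b)
    if mode == "windowed":
        win = min(11, min(a.shape) - (1 - min(a.shape) % 2))  # largest odd size that fits
        return float(
            structural_similarity(
                a,
                b,
                data_range=1.0,
                gaussian_weights=True,
                sigma=1.5,
                win_size=win,
                use_sample_covariance=False,
                K1=SSIM_K1,
                K2=SSIM_K2,
            )
        )
    if mode == "global":
        c1 = (SSIM_K1 * 1.0) ** 2
        c2 = (SSIM_K2 * 1.0) ** 2
        mu1, mu2 = a.mean(), b.mean()
        v1 = a.var(ddof=1)
        v2 = b.var(ddof=1)
        cov = float(((a - mu1) * (b - mu2)).sum() / (a.size - 1))
        return float(
            ((2 * mu1 * mu2 + c1) * (2 * cov + c2))
            / ((mu1**2 + mu2**2 + c1) * (v1 + v2 + c2))
        )
    raise ValueError("mode must be 'windowed' or 'global'")


def residual_image(
    reference: np.ndarray, denoised: np.ndarray, reference_kind: str = "ground_truth"
) -> ResidualImage:
    """|reference - denoised| min-max normalized to [0, 1] (all zeros if constant)."""
    ref = validate_image(reference, "reference")
    den = validate_image(denoised, "denoised")
    check_same_shape(ref, den)
    diff = np.abs(ref - den)
    span = diff.max() - diff.min()
    if span == 0.0:
        return ResidualImage(values=np.zeros_like(diff), reference_kind=reference_kind)
    return ResidualImage(values=(diff - diff.min()) / span, reference_kind=reference_kind)


def evaluate_set(pairs, n_bits: int = 8, ids=None) -> MetricReport:
    """Per-image PSNR/SSIM for (reference, denoised) pairs plus their means."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("pairs must be non-empty")
    ids = [str(i) for i in (ids if ids is not None else range(len(pairs)))]
    per_image = []
    for pid, (ref, den) in zip(ids, pairs):
        per_image.append((pid, psnr(ref, den, n_bits=n_bits), ssim(ref, den)))
    psnrs = [p for _, p, _ in per_image]
    ssims = [s for _, _, s in per_image]
    return MetricReport(
        psnr=float(np.mean(psnrs)),
        ssim=float(np.mean(ssims)),
        n_bits=n_bits,
        per_image=per_image,
    )
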