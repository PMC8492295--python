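"""Synthetic chest-radiograph-like phantoms and noise models.

The phantom generator emulates the gross statistics of a projection
radiograph: a smooth low-frequency background, a handful of bright
elliptical structures (nodule / mediastinum analogues), and at least one
ribbon running across the field (a rib analogue) that contributes sharp
edges.  It exists so the whole denoising pipeline is exercisable without
any external dataset.

Noise models cover the three corruption families used for training data:
additive Gaussian noise, salt-and-pepper impulses, and a compound
"mixed_random" corruption (Gaussian followed by salt-and-pepper).  All
operations are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import check_same_shape, clip_to_range, validate_image

MIN_PHANTOM_SIDE = 32

#: Severity preset producing noisy-vs-clean PSNR around 15-18 dB on phantoms,
#: the regime of a badly corrupted radiograph.  Tuning constants of this
#: package, not literature values.
DEFAULT_SIGMA = 0.18
DEFAULT_P_SALT = 0.02
DEFAULT_P_PEPPER = 0.02


@dataclass(frozen=True)
class NoiseSpec:
    """Declarative description of one synthetic corruption.

    kind: "gaussian", "salt_pepper" or "mixed_random".
    sigma: Gaussian standard deviation in intensity units ([0,1] scale).
    p_salt / p_pepper: per-pixel probabilities of being forced to the
        range maximum / minimum.
    seed: seed of the pseudo-random stream; same spec, same output.
    """

    kind: str
    sigma: float = 0.0
    p_salt: float = 0.0
    p_pepper: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "salt_pepper", "mixed_random"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.p_salt <= 1.0 and 0.0 <= self.p_pepper <= 1.0):
            raise ValueError("p_salt and p_pepper must lie in [0, 1]")
        if self.p_salt + self.p_pepper > 1.0:
            raise ValueError("p_salt + p_pepper must not exceed 1")


def default_noise_specs(seed: int = 0) -> list[NoiseSpec]:
    """The three-family severity preset (PSNR ~15-18 dB on phantoms)."""
    return [
        NoiseSpec("gaussian", sigma=DEFAULT_SIGMA, seed=seed),
        NoiseSpec("salt_pepper", p_salt=DEFAULT_P_SALT, p_pepper=DEFAULT_P_PEPPER, seed=seed),
        NoiseSpec(
            "mixed_random",
            sigma=DEFAULT_SIGMA,
            p_salt=DEFAULT_P_SALT,
            p_pepper=DEFAULT_P_PEPPER,
            seed=seed,
        ),
    ]


@dataclass
class PairedSample:
    """A clean/noisy training pair, optionally with its conditioning image."""

    clean: np.ndarray
    noisy: np.ndarray
    enhanced: np.ndarray | None = None
    spec: NoiseSpec | None = None

    def __post_init__(self) -> None:
        check_same_shape(self.clean, self.noisy, "clean and noisy")
        if self.enhanced is not None:
            check_same_shape(self.clean, self.enhanced, "clean and enhanced")


def make_phantom(height: int, width: int, complexity: int = 3, seed: int = 0) -> np.ndarray:
    """Generate one deterministic phantom image in [0, 1].

    Composition: smoothed random background + ``complexity`` bright
    ellipses with sharp boundaries + one sinusoidal ribbon.  The result is
    contrast-stretched so pixel standard deviation is comfortably above
    0.05 (non-degenerate contrast).
    """
    if height < MIN_PHANTOM_SIDE or width < MIN_PHANTOM_SIDE:
        raise ValueError(f"phantom sides must be >= {MIN_PHANTOM_SIDE}, got {height}x{width}")
    if complexity < 1:
        raise ValueError("complexity must be >= 1")
    rng = np.random.default_rng(seed)

    # smooth low-frequency background
    field = rng.standard_normal((height, width))
    background = ndimage.gaussian_filter(field, sigma=min(height, width) / 8.0)
    bg_span = background.max() - background.min()
    img = 0.15 + 0.25 * (background - background.min()) / max(bg_span, 1e-12)

    rows, cols = np.mgrid[0:height, 0:width].astype(np.float64)

    # bright ellipses with hard edges (lesion / mediastinum analogues)
    for _ in range(complexity):
        cy = rng.uniform(0.15, 0.85) * height
        cx = rng.uniform(0.15, 0.85) * width
        ry = rng.uniform(0.06, 0.2) * height
        rx = rng.uniform(0.06, 0.2) * width
        theta = rng.uniform(0.0, np.pi)
        dy, dx = rows - cy, cols - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        img = img + rng.uniform(0.25, 0.5) * mask

    # one ribbon with sharp edges (rib analogue)
    center = rng.uniform(0.25, 0.75) * height
    amplitude = rng.uniform(0.05, 0.15) * height
    period = rng.uniform(0.5, 1.5)
    phase = rng.uniform(0.0, 2 * np.pi)
    thickness = max(1.0, rng.uniform(0.02, 0.05) * height)
    line = center + amplitude * np.sin(2 * np.pi * period * np.arange(width) / width + phase)
    ribbon = np.abs(rows - line[None, :]) <= thickness
    img = img + rng.uniform(0.2, 0.35) * ribbon

    # contrast-stretch into [0.02, 0.98]
    img = (img - img.min()) / max(img.max() - img.min(), 1e-12)
    img = 0.02 + 0.96 * img
    return validate_image(img, "phantom")


def add_noise(clean: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Corrupt ``clean`` according to ``spec``; clipped to [0, 1], same shape."""
    arr = validate_image(clean, "clean")
    rng = np.random.default_rng(spec.seed)
    out = arr
    if spec.kind in ("gaussian", "mixed_random"):
        out = out + rng.normal(0.0, spec.sigma, size=arr.shape)
    if spec.kind in ("salt_pepper", "mixed_random"):
        u = rng.random(arr.shape)
        out = np.where(u < spec.p_salt, 1.0, out)
        out = np.where((u >= spec.p_salt) & (u < spec.p_salt + spec.p_pepper), 0.0, out)
    return clip_to_range(out)


def make_dataset(
    n_pairs: int,
    height: int,
    width: int,
    specs: list[NoiseSpec],
    seed: int = 0,
) -> list[PairedSample]:
    """Build ``n_pairs`` clean/noisy pairs with distinct phantoms.

    The noise spec for each pair is drawn from ``specs`` by the seeded
    stream, and each application gets its own derived noise seed, so two
    pairs sharing a spec family still see independent corruption.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    samples: list[PairedSample] = []
    for _ in range(n_pairs):
        phantom_seed = int(rng.integers(0, 2**31 - 1))
        complexity = int(rng.integers(2, 6))
        clean = make_phantom(height, width, complexity=complexity, seed=phantom_seed)
        base = specs[int(rng.integers(0, len(specs)))]
        spec = dataclasses.replace(base, seed=int(rng.integers(0, 2**31 - 1)))
        samples.append(PairedSample(clean=clean, noisy=add_noise(clean, spec), spec=spec))
    return samples
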