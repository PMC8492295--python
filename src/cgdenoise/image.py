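"""Image conventions and grayscale PNG/TIFF IO.

Throughout the package an image is a 2-D ``numpy.ndarray`` of floating
intensities in the canonical range [0, 1].  Metrics that need an integer
dynamic range (PSNR) rescale by ``2**n_bits - 1`` at computation time;
nothing is ever quantized internally.  Images must be at least 2x2 so the
forward-difference gradient operators have one neighbor to look at.
"""

from __future__ import annotations

import numpy as np

VALUE_MIN = 0.0
VALUE_MAX = 1.0
MIN_SIDE = 2


def validate_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Check the Image2D contract and return the array as float64.

    Raises ``ValueError`` on wrong rank, undersized grids, non-finite
    entries, or intensities outside [0, 1].
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise ValueError(f"{name} must be at least {MIN_SIDE}x{MIN_SIDE}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if arr.min() < VALUE_MIN or arr.max() > VALUE_MAX:
        raise ValueError(
            f"{name} intensities must lie in [{VALUE_MIN}, {VALUE_MAX}]; "
            f"got [{arr.min():.4g}, {arr.max():.4g}]"
        )
    return arr


def check_same_shape(a: np.ndarray, b: np.ndarray, what: str = "images") -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what} must have identical dimensions: {a.shape} vs {b.shape}")


def clip_to_range(img: np.ndarray) -> np.ndarray:
    """Clip (never wrap) intensities into [0, 1] — detector saturation semantics."""
    return np.clip(img, VALUE_MIN, VALUE_MAX)


def read_image(path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF into a [0, 1] float image."""
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:  # collapse any color axis; inputs are expected grayscale
        raw = raw[..., 0]
    if np.issubdtype(raw.dtype, np.integer):
        peak = float(np.iinfo(raw.dtype).max)
        img = raw.astype(np.float64) / peak
    else:
        img = raw.astype(np.float64)
    return validate_image(clip_to_range(img), name=str(path))


def write_image(path, img: np.ndarray, bits: int = 8) -> None:
    """Write a [0, 1] float image as an 8- or 16-bit grayscale file."""
    import imageio.v3 as iio

    arr = validate_image(img)
    if bits == 8:
        out = np.round(arr * 255.0).astype(np.uint8)
    elif bits == 16:
        out = np.round(arr * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    iio.imwrite(path, out)
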