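"""RGB <-> HSI conversion and intensity-channel plumbing.

The enhancement pipeline operates on the intensity channel of the
hue-saturation-intensity (HSI) colour model, in which intensity is the
plain mean of the three RGB channels, I = (R + G + B) / 3 (Gonzalez
sector convention).  Hue and saturation are carried through unchanged so
that a contrast-stretched intensity channel can be recombined with them
and converted back to RGB without shifting the perceived colour.

All images are floating point with channel values in [0, 1].  Hue is
stored in radians in [0, 2*pi); achromatic pixels (saturation zero, or a
degenerate hue denominator) carry a sentinel hue of 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "HSIImage",
    "rgb_to_hsi",
    "hsi_to_rgb",
    "replace_intensity",
    "intensity_channel",
    "load_image",
    "save_image",
]

_TWO_PI = 2.0 * np.pi
_THIRD_PI = np.pi / 3.0


@dataclass
class HSIImage:
    """An image in HSI coordinates; all three planes share one shape."""

    hue: np.ndarray  # radians in [0, 2*pi); 0 at achromatic pixels
    saturation: np.ndarray  # in [0, 1]
    intensity: np.ndarray  # in [0, 1]

    def __post_init__(self) -> None:
        if not (self.hue.shape == self.saturation.shape == self.intensity.shape):
            raise ValueError("HSI planes must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


def _validate_rgb(image) -> np.ndarray:
    rgb = np.asarray(image, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (rows, cols, 3) RGB array, got shape {rgb.shape}")
    if rgb.shape[0] == 0 or rgb.shape[1] == 0:
        raise ValueError("empty image")
    return rgb


def rgb_to_hsi(image) -> HSIImage:
    """Convert an RGB array in [0,1] to HSI (Gonzalez sector formulas)."""
    rgb = _validate_rgb(image)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = r + g + b
    intensity = total / 3.0

    min_channel = rgb.min(axis=-1)
    saturation = np.zeros_like(intensity)
    np.divide(3.0 * min_channel, total, out=saturation, where=total > 0)
    saturation = np.clip(1.0 - saturation, 0.0, 1.0)
    saturation[total <= 0] = 0.0

    numerator = 0.5 * ((r - g) + (r - b))
    denominator = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    chromatic = (denominator > 1e-12) & (saturation > 1e-12)
    cos_arg = np.zeros_like(numerator)
    np.divide(numerator, denominator, out=cos_arg, where=chromatic)
    theta = np.arccos(np.clip(cos_arg, -1.0, 1.0))
    hue = np.where(b > g, _TWO_PI - theta, theta)
    hue = np.where(chromatic, hue, 0.0)

    return HSIImage(hue=hue, saturation=saturation, intensity=intensity)


def _sector(h: np.ndarray, s: np.ndarray, i: np.ndarray):
    """One 120-degree sector of the inverse conversion.

    Returns the (low, boosted, remainder) channel triple for a sector-local
    hue ``h`` in [0, 2*pi/3).
    """
    low = i * (1.0 - s)
    boosted = i * (1.0 + s * np.cos(h) / np.cos(_THIRD_PI - h))
    remainder = 3.0 * i - low - boosted
    return low, boosted, remainder


def hsi_to_rgb(image: HSIImage) -> np.ndarray:
    """Invert :func:`rgb_to_hsi`; outputs are clipped to [0, 1]."""
    h = np.mod(np.asarray(image.hue, dtype=float), _TWO_PI)
    s = np.asarray(image.saturation, dtype=float)
    i = np.asarray(image.intensity, dtype=float)
    if h.shape[0] == 0 or h.ndim != 2:
        raise ValueError("empty or non-2D HSI image")

    r = np.empty_like(i)
    g = np.empty_like(i)
    b = np.empty_like(i)

    sector_width = _TWO_PI / 3.0
    # (mask, hue offset, channel order): within each sector one channel sits
    # at I(1-S), one carries the chroma boost, the third takes the remainder.
    rg_sector = h < sector_width
    gb_sector = (h >= sector_width) & (h < 2 * sector_width)
    br_sector = h >= 2 * sector_width

    for mask, offset, order in (
        (rg_sector, 0.0, (b, r, g)),
        (gb_sector, sector_width, (r, g, b)),
        (br_sector, 2 * sector_width, (g, b, r)),
    ):
        if not mask.any():
            continue
        low, boosted, remainder = _sector(h[mask] - offset, s[mask], i[mask])
        order[0][mask] = low
        order[1][mask] = boosted
        order[2][mask] = remainder

    return np.clip(np.stack([r, g, b], axis=-1), 0.0, 1.0)


def replace_intensity(image: HSIImage, enhanced) -> HSIImage:
    """Return a copy of ``image`` with its intensity plane swapped out."""
    enhanced = np.asarray(enhanced, dtype=float)
    if enhanced.shape != image.shape:
        raise ValueError(
            f"enhanced channel shape {enhanced.shape} != image shape {image.shape}"
        )
    return HSIImage(
        hue=image.hue.copy(),
        saturation=image.saturation.copy(),
        intensity=enhanced.copy(),
    )


def intensity_channel(image) -> np.ndarray:
    """Mean of the RGB channels, the I plane of HSI."""
    return _validate_rgb(image).mean(axis=-1)


def load_image(path) -> np.ndarray:
    """Read PNG/JPEG/TIFF into a float RGB array in [0,1].

    8- and 16-bit integer inputs are rescaled by their type maximum;
    grayscale is replicated to three channels and alpha is dropped.
    """
    arr = iio.imread(Path(path))
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(float), 0.0, 1.0)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return _validate_rgb(arr)


def save_image(path, image) -> None:
    """Write a float RGB array in [0,1] as an 8-bit image file."""
    rgb = _validate_rgb(image)
    quantized = np.round(np.clip(rgb, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(Path(path), quantized)
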