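"""Synthetic low-contrast dermoscopy-like fixtures with ground truth.

Generates a skin-toned background carrying a darker, blurred elliptical
lesion, additive Gaussian noise and optional dark hair streaks, paired
with the exact (pre-blur) ellipse indicator as the ground-truth mask.
The defaults deliberately mimic poor-contrast dermoscopy: the
lesion/background intensity gap is small relative to the noise and blur,
so plain threshold segmentation visibly degrades on the raw images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line_aa

from .color_model import save_image

__all__ = [
    "SyntheticLesionSpec",
    "DatasetRanges",
    "LabeledSample",
    "ellipse_mask",
    "generate_lesion",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticLesionSpec:
    """Full description of one synthetic sample (pixel units, [0,1] intensities)."""

    height: int = 128
    width: int = 128
    background_intensity: float = 0.65
    background_tint: tuple[float, float, float] = (0.10, 0.0, -0.10)  # zero-mean
    center: tuple[float, float] = (64.0, 64.0)  # (row, col)
    semi_axes: tuple[float, float] = (26.0, 20.0)
    rotation: float = 0.5  # radians
    contrast_gap: float = 0.12
    blur_sigma: float = 2.0
    noise_sigma: float = 0.02
    n_hairs: int = 2
    hair_opacity: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast_gap <= 0:
            raise ValueError("contrast gap must be positive")
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")


@dataclass
class LabeledSample:
    """Synthetic RGB image plus its binary lesion mask (1 = lesion)."""

    image: np.ndarray
    mask: np.ndarray
    spec: SyntheticLesionSpec


def _extents(spec: SyntheticLesionSpec) -> tuple[float, float]:
    """Max |row|, |col| offsets of the rotated ellipse from its center."""
    a, b = spec.semi_axes
    cos_r, sin_r = np.cos(spec.rotation), np.sin(spec.rotation)
    dr = np.hypot(a * cos_r, b * sin_r)
    dc = np.hypot(a * sin_r, b * cos_r)
    return dr, dc


def ellipse_mask(spec: SyntheticLesionSpec) -> np.ndarray:
    """Exact pixel-membership indicator of the (rotated) lesion ellipse."""
    cr, cc = spec.center
    dr, dc = _extents(spec)
    if cr - dr < 0 or cr + dr > spec.height - 1 or cc - dc < 0 or cc + dc > spec.width - 1:
        raise ValueError("lesion ellipse extends outside the image")
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width]
    y, x = rows - cr, cols - cc
    cos_r, sin_r = np.cos(spec.rotation), np.sin(spec.rotation)
    major = y * cos_r + x * sin_r
    minor = -y * sin_r + x * cos_r
    a, b = spec.semi_axes
    return (major / a) ** 2 + (minor / b) ** 2 <= 1.0


def _draw_hair(image: np.ndarray, rng: np.random.Generator, opacity: float) -> None:
    """Darken pixels along one anti-aliased quadratic curve, in place."""
    h, w = image.shape[:2]
    control = rng.uniform([0, 0], [h - 1, w - 1], size=(3, 2))
    t = np.linspace(0.0, 1.0, 64)[:, None]
    points = (
        (1 - t) ** 2 * control[0] + 2 * (1 - t) * t * control[1] + t**2 * control[2]
    )
    points = np.round(points).astype(int)
    hair_color = np.array([0.18, 0.14, 0.12])
    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        rr, cc, val = line_aa(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc, val = rr[keep], cc[keep], val[keep]
        alpha = (val * opacity)[:, None]
        image[rr, cc] = (1 - alpha) * image[rr, cc] + alpha * hair_color


def generate_lesion(spec: SyntheticLesionSpec) -> LabeledSample:
    """Render one sample; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    mask = ellipse_mask(spec)

    background = spec.background_intensity + np.asarray(spec.background_tint)
    image = np.broadcast_to(background, (spec.height, spec.width, 3)).astype(float).copy()
    image[mask] -= spec.contrast_gap

    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    for _ in range(spec.n_hairs):
        _draw_hair(image, rng, spec.hair_opacity)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)

    return LabeledSample(image=np.clip(image, 0.0, 1.0), mask=mask, spec=spec)


@dataclass(frozen=True)
class DatasetRanges:
    """Uniform sampling ranges for dataset generation (inclusive)."""

    background_intensity: tuple[float, float] = (0.60, 0.70)
    contrast_gap: tuple[float, float] = (0.10, 0.14)
    blur_sigma: tuple[float, float] = (1.5, 2.5)
    noise_sigma: tuple[float, float] = (0.015, 0.025)
    semi_axis: tuple[float, float] = (16.0, 32.0)
    rotation: tuple[float, float] = (0.0, np.pi)
    n_hairs: tuple[int, int] = (0, 3)

    def __post_init__(self) -> None:
        for name in ("background_intensity", "contrast_gap", "blur_sigma",
                     "noise_sigma", "semi_axis", "rotation", "n_hairs"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"empty range for {name}")


def generate_dataset(
    n: int,
    ranges: DatasetRanges | None = None,
    seed: int | None = None,
    base_spec: SyntheticLesionSpec | None = None,
) -> list[LabeledSample]:
    """Draw ``n`` reproducible samples with specs uniform over ``ranges``."""
    if n < 1:
        raise ValueError("need at least one sample")
    ranges = ranges or DatasetRanges()
    base_spec = base_spec or SyntheticLesionSpec()
    rng = np.random.default_rng(seed)

    samples = []
    for _ in range(n):
        axis_a = rng.uniform(*ranges.semi_axis)
        axis_b = rng.uniform(*ranges.semi_axis)
        margin = max(axis_a, axis_b) + 2.0
        if 2 * margin >= min(base_spec.height, base_spec.width) - 1:
            raise ValueError(
                "semi_axis range too large for the image size; "
                "shrink DatasetRanges.semi_axis or enlarge the base spec"
            )
        spec = replace(
            base_spec,
            background_intensity=rng.uniform(*ranges.background_intensity),
            contrast_gap=rng.uniform(*ranges.contrast_gap),
            blur_sigma=rng.uniform(*ranges.blur_sigma),
            noise_sigma=rng.uniform(*ranges.noise_sigma),
            semi_axes=(axis_a, axis_b),
            rotation=rng.uniform(*ranges.rotation),
            center=(
                rng.uniform(margin, base_spec.height - 1 - margin),
                rng.uniform(margin, base_spec.width - 1 - margin),
            ),
            n_hairs=int(rng.integers(ranges.n_hairs[0], ranges.n_hairs[1] + 1)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        samples.append(generate_lesion(spec))
    return samples


def write_dataset(samples: list[LabeledSample], out_dir) -> pd.DataFrame:
    """Write image/mask PNG pairs plus a manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sample in enumerate(samples):
        image_name = f"image_{i:03d}.png"
        mask_name = f"mask_{i:03d}.png"
        save_image(out_dir / image_name, sample.image)
        save_image(
            out_dir / mask_name,
            np.stack([sample.mask.astype(float)] * 3, axis=-1),
        )
        rows.append(
            {
                "sample_id": i,
                "image": image_name,
                "mask": mask_name,
                "contrast_gap": sample.spec.contrast_gap,
                "noise_sigma": sample.spec.noise_sigma,
                "blur_sigma": sample.spec.blur_sigma,
                "n_hairs": sample.spec.n_hairs,
                "seed": sample.spec.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
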