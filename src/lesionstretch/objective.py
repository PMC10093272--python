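"""Edge/entropy image-quality objective for contrast enhancement.

A well-contrasted image exposes many edge pixels ("edgels"), strong
gradient magnitudes and a spread-out histogram.  The objective combines
the three:

    CF = log(log(Ys)) * n_edgels * H / (P * R)

where Ys is the summed Sobel gradient magnitude over the channel,
n_edgels counts pixels whose gradient magnitude exceeds a threshold,
H is the Shannon histogram entropy (bits), and P x R normalizes by the
pixel count.  The double natural log damps the gradient term so the
optimizer is not rewarded for runaway over-stretching.

Degenerate inputs are safe: Ys is floored just above e before the double
log (log(log(x)) is undefined at or below 1 and negative below e), and a
constant channel scores exactly 0 because its entropy and edgel count
both vanish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SOBEL_H",
    "SOBEL_V",
    "SobelField",
    "ObjectiveConfig",
    "CostBreakdown",
    "sobel_gradients",
    "count_edgels",
    "entropy",
    "cost_function",
]

#: Horizontal-derivative Sobel kernel (responds to vertical edges).
SOBEL_H = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
#: Vertical-derivative Sobel kernel.
SOBEL_V = SOBEL_H.T.copy()

#: Floor for the gradient sum before log(log(.)).
_LOG_GUARD = np.e + 1e-12


@dataclass
class SobelField:
    """Sobel derivative responses and their Euclidean magnitude."""

    horizontal: np.ndarray
    vertical: np.ndarray
    magnitude: np.ndarray

    @property
    def gradient_sum(self) -> float:
        """Ys: summed gradient magnitude over all pixels."""
        return float(self.magnitude.sum())


@dataclass(frozen=True)
class ObjectiveConfig:
    """Knobs of the quality objective.

    edgel_threshold: ``"mean"`` uses the mean gradient magnitude of the
    field (self-scaling across contrast levels); a float is used as an
    absolute magnitude threshold.
    """

    bins: int = 256
    edgel_threshold: str | float = "mean"

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("at least 2 histogram bins required")
        if isinstance(self.edgel_threshold, str) and self.edgel_threshold != "mean":
            raise ValueError(f"unknown edgel threshold rule {self.edgel_threshold!r}")


@dataclass
class CostBreakdown:
    """The objective value together with its three ingredients."""

    gradient_sum: float  # Ys
    n_edgels: int
    entropy: float  # bits
    cf: float
    shape: tuple[int, int]


def sobel_gradients(channel) -> SobelField:
    """Convolve with the 3x3 Sobel pair (reflect padding)."""
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("intensity channel must be 2-D")
    if min(channel.shape) < 3:
        raise ValueError(
            f"channel of shape {channel.shape} is smaller than the 3x3 kernel"
        )
    horizontal = ndimage.convolve(channel, SOBEL_H, mode="reflect")
    vertical = ndimage.convolve(channel, SOBEL_V, mode="reflect")
    return SobelField(
        horizontal=horizontal,
        vertical=vertical,
        magnitude=np.hypot(horizontal, vertical),
    )


def count_edgels(field: SobelField, threshold: str | float = "mean") -> int:
    """Number of pixels whose gradient magnitude strictly exceeds the threshold."""
    if isinstance(threshold, str):
        if threshold != "mean":
            raise ValueError(f"unknown edgel threshold rule {threshold!r}")
        cut = float(field.magnitude.mean())
    else:
        cut = float(threshold)
    return int(np.count_nonzero(field.magnitude > cut))


def entropy(channel, bins: int = 256) -> float:
    """Shannon entropy (bits) of the equal-width histogram on [0, 1]."""
    if bins < 2:
        raise ValueError("at least 2 histogram bins required")
    channel = np.clip(np.asarray(channel, dtype=float), 0.0, 1.0)
    indices = np.minimum((channel * bins).astype(np.intp), bins - 1)
    counts = np.bincount(indices.ravel(), minlength=bins)
    p = counts[counts > 0] / channel.size
    return float(-(p * np.log2(p)).sum())


def cost_function(channel, config: ObjectiveConfig | None = None) -> CostBreakdown:
    """Evaluate CF and its breakdown on an intensity channel."""
    config = config or ObjectiveConfig()
    channel = np.asarray(channel, dtype=float)
    field = sobel_gradients(channel)
    gradient_sum = field.gradient_sum
    n_edgels = count_edgels(field, config.edgel_threshold)
    h = entropy(channel, config.bins)
    rows, cols = channel.shape
    double_log = np.log(np.log(max(gradient_sum, _LOG_GUARD)))
    cf = double_log * n_edgels * h / (rows * cols)
    return CostBreakdown(
        gradient_sum=gradient_sum,
        n_edgels=n_edgels,
        entropy=h,
        cf=float(cf),
        shape=(rows, cols),
    )
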