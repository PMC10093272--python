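"""Local-statistics contrast stretching of an intensity channel.

The transform maps an intensity channel f(x, y) to

    g(x, y) = [Pd * mu / (sigma(x, y) + Pb + eps)] * (f(x, y) - Pg * m(x, y))
              + m(x, y) ** Pa

where m and sigma are the sliding-window local mean and (population)
standard deviation, mu is the global mean, and (Pa, Pb, Pg, Pd) is the
four-element parameter vector estimated per image by the optimizer:

    Pa  exponent on the local mean (smoothness / brightness term)
    Pb  denominator offset (caps the gain on flat regions)
    Pg  local-mean subtraction weight (how much local background to remove)
    Pd  overall gain

Pixels far from their local mean get amplified by a gain inversely
proportional to the local spread, which stretches low-contrast detail;
the additive m**Pa term restores local brightness.  Output is clipped to
[0, 1] and keeps the input shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ParameterBounds",
    "DEFAULT_BOUNDS",
    "LocalStats",
    "local_statistics",
    "apply_transform",
    "clip_to_bounds",
]

#: Guard added to the gain denominator; Pb may be 0 and sigma vanishes on
#: flat regions, where the gain would otherwise be unbounded.
EPS_GUARD = 1e-6


@dataclass(frozen=True)
class ParameterBounds:
    """Componentwise box bounds for the (Pa, Pb, Pg, Pd) vector."""

    lower: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 0.0, 0.5])
    )
    upper: np.ndarray = field(
        default_factory=lambda: np.array([1.6, 0.5, 0.8, 1.5])
    )

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape:
            raise ValueError("bound vectors must share one shape")
        if np.any(lower > upper):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def dimension(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, params) -> np.ndarray:
        return np.clip(np.asarray(params, dtype=float), self.lower, self.upper)


DEFAULT_BOUNDS = ParameterBounds()


def clip_to_bounds(params, bounds: ParameterBounds = DEFAULT_BOUNDS) -> np.ndarray:
    """Clamp a parameter vector into the box [lower, upper]."""
    return bounds.clip(params)


@dataclass
class LocalStats:
    """Sliding-window statistics of an intensity channel."""

    mean: np.ndarray  # local mean, same shape as the channel
    std: np.ndarray  # local population standard deviation
    global_mean: float
    window: int


def local_statistics(channel, window: int = 3) -> LocalStats:
    """Per-pixel mean and population std over a window x window box.

    Borders use reflect padding so no artificial edges are introduced.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("intensity channel must be 2-D")
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if window > min(channel.shape):
        raise ValueError(
            f"window {window} does not fit in channel of shape {channel.shape}"
        )
    mean = ndimage.uniform_filter(channel, size=window, mode="reflect")
    mean_sq = ndimage.uniform_filter(channel**2, size=window, mode="reflect")
    variance = np.clip(mean_sq - mean**2, 0.0, None)
    return LocalStats(
        mean=mean,
        std=np.sqrt(variance),
        global_mean=float(channel.mean()),
        window=window,
    )


def apply_transform(
    channel, params, stats: LocalStats, eps_guard: float = EPS_GUARD
) -> np.ndarray:
    """Apply the four-parameter statistical stretch; output in [0, 1]."""
    channel = np.asarray(channel, dtype=float)
    params = np.asarray(params, dtype=float)
    if params.shape != (4,):
        raise ValueError("parameter vector must have exactly four components")
    if stats.mean.shape != channel.shape:
        raise ValueError("stats were not computed from this channel shape")
    p_alpha, p_beta, p_gamma, p_delta = params
    gain = p_delta * stats.global_mean / (stats.std + p_beta + eps_guard)
    stretched = gain * (channel - p_gamma * stats.mean) + stats.mean**p_alpha
    return np.clip(stretched, 0.0, 1.0)
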