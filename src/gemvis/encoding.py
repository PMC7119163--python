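"""Map interpolated metabolite values to per-node visual states.

Four encodings are supported, matching the visual alternatives for showing
a metabolite pool on a circular node:

* ``fill`` — the node's circle fills bottom-up; fill *height* is linear in
  the normalized value (a length-scale encoding, which readers judge most
  accurately).  Radius and color stay constant.
* ``size`` — node radius varies between ``r_min`` and ``r_max``; by default
  the *area* is linear in the value so perceived magnitude tracks the data.
* ``color`` — the node color moves along a colormap.
* ``size_color`` — radius and color together encode the value (used for
  absolute-abundance views).

Values are first normalized to [0, 1] against per-metabolite, global, or
fixed bounds; out-of-range values clip rather than rescale so frames of one
animation remain mutually comparable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EncodingConfig",
    "NodeVisualState",
    "normalize",
    "encode",
    "series_bounds",
    "DEFAULT_COLORMAP",
    "UNMEASURED_GRAY",
]

Color = tuple[float, float, float]  # RGB, 0-255 floats

#: Two-stop sequential colormap: light blue-gray to saturated red.
DEFAULT_COLORMAP: tuple[Color, ...] = ((224.0, 228.0, 236.0), (202.0, 33.0, 39.0))
UNMEASURED_GRAY: Color = (200.0, 200.0, 200.0)

_MODES = ("fill", "size", "color", "size_color")
_NORMS = ("per_metabolite", "global", "fixed")
_SIZE_LAWS = ("radius_linear", "area_linear")


@dataclass
class NodeVisualState:
    """Resolved appearance of one node at one frame time."""

    fill_fraction: float
    radius: float
    color: Color
    measured: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.fill_fraction <= 1.0:
            raise ValueError(f"fill_fraction {self.fill_fraction} outside [0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class EncodingConfig:
    """How a normalized value becomes fill fraction, radius, and color.

    ``r_base`` is the constant node radius used by modes that do not vary
    size.  ``fixed_range`` supplies (lo, hi) bounds when
    ``normalization='fixed'``.  ``log_scale`` applies log10(1 + v) to values
    and bounds before normalization.
    """

    mode: str = "fill"
    normalization: str = "per_metabolite"
    fixed_range: Optional[tuple[float, float]] = None
    r_min: float = 4.0
    r_max: float = 16.0
    r_base: float = 10.0
    colormap: tuple[Color, ...] = DEFAULT_COLORMAP
    size_law: str = "area_linear"
    base_color: Color = DEFAULT_COLORMAP[1]
    unmeasured_color: Color = UNMEASURED_GRAY
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.normalization not in _NORMS:
            raise ValueError(f"normalization must be one of {_NORMS}")
        if self.size_law not in _SIZE_LAWS:
            raise ValueError(f"size_law must be one of {_SIZE_LAWS}")
        if not self.r_min < self.r_max:
            raise ValueError(f"r_min must be < r_max, got {self.r_min} >= {self.r_max}")
        if len(self.colormap) < 2:
            raise ValueError("colormap needs at least 2 stops")
        if self.normalization == "fixed":
            if self.fixed_range is None or not self.fixed_range[0] < self.fixed_range[1]:
                raise ValueError("fixed normalization requires fixed_range with lo < hi")

    def unmeasured_state(self) -> NodeVisualState:
        """The constant state every node without data receives."""
        return NodeVisualState(
            fill_fraction=1.0,
            radius=self.r_base,
            color=self.unmeasured_color,
            measured=False,
        )


def normalize(value: float, lo: float, hi: float) -> float:
    """Linear map of ``value`` from [lo, hi] onto [0, 1], clipped.

    A degenerate range (lo == hi, e.g. a constant series) maps to 0.5.
    """
    if not math.isfinite(value):
        raise ValueError(f"cannot normalize non-finite value {value!r}")
    if lo > hi:
        raise ValueError(f"lo {lo} > hi {hi}")
    if lo == hi:
        return 0.5
    return min(1.0, max(0.0, (value - lo) / (hi - lo)))


def colormap_color(colormap: Sequence[Color], fraction: float) -> Color:
    """Piecewise-linear interpolation along evenly spaced colormap stops."""
    n = len(colormap)
    pos = fraction * (n - 1)
    i = min(int(pos), n - 2)
    t = pos - i
    a, b = colormap[i], colormap[i + 1]
    return tuple(a[k] + (b[k] - a[k]) * t for k in range(3))


def _radius(fraction: float, config: EncodingConfig) -> float:
    if config.size_law == "radius_linear":
        return config.r_min + fraction * (config.r_max - config.r_min)
    # area_linear: disk area interpolates linearly between the extremes
    return math.sqrt(config.r_min**2 + fraction * (config.r_max**2 - config.r_min**2))


def encode(
    value: float, series_lo: float, series_hi: float, config: EncodingConfig
) -> NodeVisualState:
    """Resolve one value (with its normalization bounds) to a visual state."""
    if config.log_scale:
        value = math.log10(1.0 + max(value, 0.0))
        series_lo = math.log10(1.0 + max(series_lo, 0.0))
        series_hi = math.log10(1.0 + max(series_hi, 0.0))
    fraction = normalize(value, series_lo, series_hi)
    if config.mode == "fill":
        return NodeVisualState(fraction, config.r_base, config.base_color)
    if config.mode == "size":
        return NodeVisualState(1.0, _radius(fraction, config), config.base_color)
    if config.mode == "color":
        return NodeVisualState(1.0, config.r_base, colormap_color(config.colormap, fraction))
    return NodeVisualState(  # size_color
        1.0, _radius(fraction, config), colormap_color(config.colormap, fraction)
    )


def series_bounds(
    matrix: np.ndarray, ids: Sequence[str], config: EncodingConfig
) -> dict[str, tuple[float, float]]:
    """Normalization bounds per metabolite for a frames x metabolites matrix.

    ``per_metabolite`` bounds make every series visit fill 0 and 1 during
    the animation (relative pool size); ``global`` and ``fixed`` give
    cross-metabolite comparability (absolute abundance).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != len(ids):
        raise ValueError("matrix must be n_frames x n_metabolites")
    if config.normalization == "fixed":
        lo, hi = config.fixed_range
        return {mid: (lo, hi) for mid in ids}
    with np.errstate(all="ignore"):
        if config.normalization == "global":
            lo, hi = float(np.nanmin(matrix)), float(np.nanmax(matrix))
            return {mid: (lo, hi) for mid in ids}
        return {
            mid: (float(np.nanmin(matrix[:, j])), float(np.nanmax(matrix[:, j])))
            for j, mid in enumerate(ids)
        }
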