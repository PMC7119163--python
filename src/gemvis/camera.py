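"""Keyframed camera paths: parse the camera file and move the viewport.

The camera file is a single logical record: the first value is the zoom
level, followed by a tab-separated list of x/y pairs — the top-left corners
of the camera viewport along its way across the map.  Tabs are the
canonical delimiter; commas and newlines are tolerated.

Zoom semantics: map units per output pixel, constant along the whole path
(the file format carries a single leading value).  Smaller zoom means
closer in.  The viewport's map-unit size is therefore
``pixel dimensions x zoom``.

The camera's progress parameter ``u`` in [0, 1] equals normalized animation
time: one traversal of the whole corner polyline per video, parameterized
by cumulative arc length so the on-screen panning speed is constant.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Optional, Union

import numpy as np

from .maps import Canvas

__all__ = [
    "CameraPath",
    "Viewport",
    "read_camera_file",
    "parse_camera_text",
    "viewport_at",
    "clamp_viewport",
    "CameraFormatError",
]


class CameraFormatError(ValueError):
    """The camera file does not parse to zoom + corner pairs."""


@dataclass
class Viewport:
    """The rectangle of map space shown in one frame (map units)."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("viewport width/height must be positive")


@dataclass
class CameraPath:
    """Zoom level plus the ordered viewport top-left corner keypoints."""

    zoom: float
    corners: list[tuple[float, float]]
    interpolation: str = "linear"  # or "catmull-rom"

    def __post_init__(self) -> None:
        if self.zoom <= 0:
            raise ValueError(f"zoom must be positive, got {self.zoom}")
        if not self.corners:
            raise ValueError("camera path needs at least one corner")
        for c in self.corners:
            if not (np.isfinite(c[0]) and np.isfinite(c[1])):
                raise ValueError(f"non-finite corner {c}")

    # cumulative arc length along the corner polyline, cached lazily
    _arclen: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def arclengths(self) -> np.ndarray:
        if self._arclen is None:
            pts = np.asarray(self.corners, dtype=float)
            if len(pts) == 1:
                self._arclen = np.zeros(1)
            else:
                steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                self._arclen = np.concatenate([[0.0], np.cumsum(steps)])
        return self._arclen


def parse_camera_text(text: str) -> CameraPath:
    """Parse camera-file content: leading zoom, then x/y corner pairs."""
    tokens = [t for t in re.split(r"[\t,\r\n ]+", text.strip()) if t]
    if not tokens:
        raise CameraFormatError("empty camera file")
    values = []
    for pos, tok in enumerate(tokens):
        try:
            values.append(float(tok))
        except ValueError:
            raise CameraFormatError(
                f"non-numeric token {tok!r} at position {pos + 1}"
            ) from None
    zoom, coords = values[0], values[1:]
    if zoom <= 0:
        raise CameraFormatError(f"zoom level must be positive, got {zoom}")
    if len(coords) == 0:
        raise CameraFormatError("camera file has a zoom level but no corner points")
    if len(coords) % 2 != 0:
        raise CameraFormatError(
            f"odd number of corner coordinates ({len(coords)}); x/y pairs required"
        )
    corners = [(coords[i], coords[i + 1]) for i in range(0, len(coords), 2)]
    return CameraPath(zoom=zoom, corners=corners)


def read_camera_file(source: Union[str, Path, BinaryIO]) -> CameraPath:
    """Read a camera definition file (tab-separated canonical dialect)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        data = source.read()
        text = data.decode("utf-8") if isinstance(data, bytes) else data
    return parse_camera_text(text)


def _catmull_rom(pts: np.ndarray, i: int, t: float) -> np.ndarray:
    """Centripetal-free (uniform) Catmull-Rom point on leg i at local t."""
    p0 = pts[max(i - 1, 0)]
    p1 = pts[i]
    p2 = pts[i + 1]
    p3 = pts[min(i + 2, len(pts) - 1)]
    t2, t3 = t * t, t * t * t
    return 0.5 * (
        (2 * p1)
        + (-p0 + p2) * t
        + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t2
        + (-p0 + 3 * p1 - 3 * p2 + p3) * t3
    )


def _position(path: CameraPath, u: float) -> tuple[float, float]:
    pts = np.asarray(path.corners, dtype=float)
    if len(pts) == 1:
        return (float(pts[0, 0]), float(pts[0, 1]))
    arclen = path.arclengths()
    total = arclen[-1]
    if total == 0.0:  # all corners coincide
        return (float(pts[0, 0]), float(pts[0, 1]))
    u = min(1.0, max(0.0, float(u)))
    s = u * total
    i = int(np.searchsorted(arclen, s, side="right") - 1)
    i = min(i, len(pts) - 2)
    leg = arclen[i + 1] - arclen[i]
    t = 0.0 if leg == 0 else (s - arclen[i]) / leg
    if path.interpolation == "catmull-rom":
        p = _catmull_rom(pts, i, t)
    else:
        p = pts[i] + t * (pts[i + 1] - pts[i])
    return (float(p[0]), float(p[1]))


def viewport_at(
    path: CameraPath, u: float, output_pixel_dims: tuple[int, int]
) -> Viewport:
    """Viewport at normalized path position ``u`` in [0, 1].

    The top-left corner moves along the corner polyline at constant speed
    (cumulative-arc-length parameterization); u=0 is the first corner and
    u=1 the last.  Size is ``pixel dims x zoom`` in map units.
    """
    x, y = _position(path, u)
    w_px, h_px = output_pixel_dims
    return Viewport(x=x, y=y, width=w_px * path.zoom, height=h_px * path.zoom)


def clamp_viewport(vp: Viewport, canvas: Canvas, policy: str = "free") -> Viewport:
    """Optionally keep the viewport on the canvas.

    ``free`` (default) trusts the camera file's corners verbatim; ``clamp``
    translates the viewport minimally to lie within the canvas, centering it
    on the canvas when it does not fit.
    """
    if policy == "free":
        return vp
    if policy != "clamp":
        raise ValueError(f"unknown clamp policy {policy!r}")

    def clamp_axis(pos: float, size: float, c0: float, csize: float) -> float:
        if size >= csize:
            return c0 + (csize - size) / 2.0  # center on canvas
        return min(max(pos, c0), c0 + csize - size)

    return Viewport(
        x=clamp_axis(vp.x, vp.width, canvas.x, canvas.width),
        y=clamp_axis(vp.y, vp.height, canvas.y, canvas.height),
        width=vp.width,
        height=vp.height,
    )
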