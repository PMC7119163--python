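"""Deterministic rasterization of one animation frame.

A frame shows the part of the map inside the current viewport, with every
metabolite node drawn according to its visual state.  Two drawing styles
are available: ``escher`` (plain curved edges, circles at metabolites,
reaction markers invisible joints) and ``sbgn`` (process-description
subset: simple-chemical circles plus a small process square on each
reaction's midmarker).

Rendering is split into two deterministic stages so tests can inspect
either: :func:`build_draw_commands` produces an ordered command stream in
output-pixel coordinates (z-order: edges < nodes < labels < legend), and
:func:`rasterize` replays it with Pillow.  Anti-aliasing is fixed integer
supersampling followed by box downsampling — identical inputs give
bit-identical rasters on any platform.

The world-to-pixel transform is ``px = (x - vp.x) / zoom`` with
``zoom = vp.width / pixel_width`` (screen orientation, y down).

Fill-level glyphs fill the circle bottom-up: the fill *height* equals
``fill_fraction x diameter`` (a circular segment below the horizontal
chord at that height).  Height, not area, is linear in the fraction — a
length-scale encoding, which beholders judge most accurately.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .camera import Viewport
from .encoding import Color, EncodingConfig, NodeVisualState, colormap_color
from .maps import MetabolicMap, bezier_point

__all__ = [
    "RenderStyle",
    "Frame",
    "render_frame",
    "render_sbgn_frame",
    "build_draw_commands",
    "rasterize",
    "draw_filled_node",
    "compose_legend",
]

_BEZIER_SAMPLES = 32


@dataclass
class RenderStyle:
    """Visual parameters of the rasterizer."""

    style: str = "escher"  # or "sbgn"
    width: int = 640
    height: int = 480
    background: Color = (255.0, 255.0, 255.0)
    edge_color: Color = (120.0, 120.0, 120.0)
    edge_width: float = 2.0
    outline_color: Color = (60.0, 60.0, 60.0)
    outline_width: float = 1.5
    node_fill_background: Color = (255.0, 255.0, 255.0)
    label_color: Color = (40.0, 40.0, 40.0)
    font_size: int = 10
    draw_labels: bool = False
    supersampling: int = 2
    process_square_px: float = 6.0  # SBGN process glyph edge length

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("pixel dimensions must be positive")
        if self.supersampling < 1 or int(self.supersampling) != self.supersampling:
            raise ValueError("supersampling must be an integer >= 1")


@dataclass
class Frame:
    """One rendered RGB raster plus its animation bookkeeping."""

    image: np.ndarray  # (H, W, 3) uint8
    index: int = 0
    data_time: float = 0.0

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("frame image must be H x W x 3")

    @property
    def size(self) -> tuple[int, int]:
        return (self.image.shape[1], self.image.shape[0])

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.image, "RGB")


# ---------------------------------------------------------------------------
# command building


def draw_filled_node(
    center_px: tuple[float, float],
    radius_px: float,
    fill_fraction: float,
    fill_color: Color,
    outline_color: Color,
    outline_width: float,
    background: Color,
) -> list[tuple]:
    """Draw commands for one fill-level node glyph.

    The interior fills bottom-up to height ``fill_fraction x 2r`` — the
    circular segment below the horizontal chord at that height.  The
    outline circle is always drawn on top.
    """
    if not 0.0 <= fill_fraction <= 1.0:
        raise ValueError(f"fill_fraction {fill_fraction} outside [0, 1]")
    cmds: list[tuple] = [("disk", center_px, radius_px, background)]
    if fill_fraction > 0.0:
        cmds.append(("circular_segment", center_px, radius_px, fill_fraction, fill_color))
    cmds.append(("circle_outline", center_px, radius_px, outline_color, outline_width))
    return cmds


def _to_px(x: float, y: float, vp: Viewport, style: RenderStyle) -> tuple[float, float]:
    sx = style.width / vp.width
    sy = style.height / vp.height
    return ((x - vp.x) * sx, (y - vp.y) * sy)


def build_draw_commands(
    metabolic_map: MetabolicMap,
    states: dict[str, NodeVisualState],
    vp: Viewport,
    style: RenderStyle,
    config: Optional[EncodingConfig] = None,
) -> list[tuple]:
    """Ordered draw command stream for one frame (edges < nodes < labels).

    ``states`` maps *node ids* of measured metabolite nodes to their visual
    states; every other metabolite node receives the encoding's constant
    unmeasured style.  Glyphs wholly outside the viewport emit nothing.
    """
    config = config or EncodingConfig()
    unmeasured = config.unmeasured_state()
    cmds: list[tuple] = []
    W, H = style.width, style.height
    margin = max(style.edge_width, style.outline_width) * 2

    def visible_box(xs, ys, pad: float) -> bool:
        return not (
            max(xs) < -pad or min(xs) > W + pad or max(ys) < -pad or min(ys) > H + pad
        )

    # edges first (lowest z)
    for edge in metabolic_map.reactions.values():
        for seg in edge.segments:
            a = metabolic_map.nodes[seg.from_node_id]
            b = metabolic_map.nodes[seg.to_node_id]
            p0 = _to_px(a.x, a.y, vp, style)
            p3 = _to_px(b.x, b.y, vp, style)
            if seg.is_bezier:
                b1 = _to_px(*seg.b1, vp, style)
                b2 = _to_px(*seg.b2, vp, style)
                xs = [p0[0], b1[0], b2[0], p3[0]]
                ys = [p0[1], b1[1], b2[1], p3[1]]
                if not visible_box(xs, ys, margin):
                    continue
                pts = [
                    bezier_point(p0, b1, b2, p3, t)
                    for t in np.linspace(0.0, 1.0, _BEZIER_SAMPLES)
                ]
            else:
                xs = [p0[0], p3[0]]
                ys = [p0[1], p3[1]]
                if not visible_box(xs, ys, margin):
                    continue
                pts = [p0, p3]
            cmds.append(("polyline", pts, style.edge_color, style.edge_width))

    # SBGN: one process square per reaction, on its midmarker (fallback:
    # mean of segment endpoints when the map has no midmarker)
    if style.style == "sbgn":
        half = style.process_square_px / 2.0
        for edge in metabolic_map.reactions.values():
            mids = [
                metabolic_map.nodes[nid]
                for nid in {s.from_node_id for s in edge.segments}
                | {s.to_node_id for s in edge.segments}
                if metabolic_map.nodes[nid].kind == "midmarker"
            ]
            if mids:
                cx, cy = mids[0].x, mids[0].y
            else:
                pts = [
                    metabolic_map.nodes[nid]
                    for s in edge.segments
                    for nid in (s.from_node_id, s.to_node_id)
                ]
                cx = sum(p.x for p in pts) / len(pts)
                cy = sum(p.y for p in pts) / len(pts)
            px, py = _to_px(cx, cy, vp, style)
            if visible_box([px - half, px + half], [py - half, py + half], margin):
                cmds.append(
                    (
                        "square",
                        (px, py),
                        half,
                        style.node_fill_background,
                        style.outline_color,
                        style.outline_width,
                    )
                )

    # metabolite nodes
    for node in metabolic_map.metabolite_nodes():
        state = states.get(node.node_id, unmeasured)
        px, py = _to_px(node.x, node.y, vp, style)
        r = state.radius
        if not visible_box([px - r, px + r], [py - r, py + r], margin):
            continue
        cmds.extend(
            draw_filled_node(
                (px, py),
                r,
                state.fill_fraction,
                state.color,
                style.outline_color,
                style.outline_width,
                style.node_fill_background,
            )
        )

    # labels (highest z below legend)
    if style.draw_labels:
        for node in metabolic_map.metabolite_nodes():
            lx = node.label_x if node.label_x is not None else node.x + 12
            ly = node.label_y if node.label_y is not None else node.y - 4
            px, py = _to_px(lx, ly, vp, style)
            if visible_box([px], [py], 100):
                cmds.append(
                    ("text", (px, py), node.display_name or node.bigg_id,
                     style.label_color, style.font_size)
                )
        for label in metabolic_map.text_labels:
            px, py = _to_px(label.x, label.y, vp, style)
            if visible_box([px], [py], 100):
                cmds.append(("text", (px, py), label.text, style.label_color, style.font_size))
    return cmds


# ---------------------------------------------------------------------------
# rasterization


def _rgb(color: Color) -> tuple[int, int, int]:
    return tuple(int(round(min(255.0, max(0.0, c)))) for c in color)


def rasterize(commands: Sequence[tuple], style: RenderStyle) -> np.ndarray:
    """Replay a command stream onto an RGB raster (supersampled, then box-
    downsampled for deterministic anti-aliasing)."""
    s = int(style.supersampling)
    W, H = style.width * s, style.height * s
    img = Image.new("RGB", (W, H), _rgb(style.background))
    draw = ImageDraw.Draw(img)

    for cmd in commands:
        op = cmd[0]
        if op == "polyline":
            _, pts, color, width = cmd
            pts_s = [(x * s, y * s) for x, y in pts]
            draw.line(pts_s, fill=_rgb(color), width=max(1, int(round(width * s))))
        elif op == "disk":
            _, (cx, cy), r, color = cmd
            cx, cy, r = cx * s, cy * s, r * s
            draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=_rgb(color))
        elif op == "circular_segment":
            _, (cx, cy), r, fraction, color = cmd
            cx, cy, r = cx * s, cy * s, r * s
            bbox = [cx - r, cy - r, cx + r, cy + r]
            if fraction >= 1.0:
                draw.ellipse(bbox, fill=_rgb(color))
            elif fraction > 0.0:
                # fill below the horizontal chord at height = fraction * 2r
                alpha = math.degrees(math.asin(min(1.0, max(-1.0, 1.0 - 2.0 * fraction))))
                draw.chord(bbox, alpha, 180.0 - alpha, fill=_rgb(color))
        elif op == "circle_outline":
            _, (cx, cy), r, color, width = cmd
            cx, cy, r = cx * s, cy * s, r * s
            draw.ellipse(
                [cx - r, cy - r, cx + r, cy + r],
                outline=_rgb(color),
                width=max(1, int(round(width * s))),
            )
        elif op == "square":
            _, (cx, cy), half, fill, outline, width = cmd
            cx, cy, half = cx * s, cy * s, half * s
            draw.rectangle(
                [cx - half, cy - half, cx + half, cy + half],
                fill=_rgb(fill),
                outline=_rgb(outline),
                width=max(1, int(round(width * s))),
            )
        elif op == "rect":
            _, (x0, y0, x1, y1), color = cmd
            draw.rectangle([x0 * s, y0 * s, x1 * s, y1 * s], fill=_rgb(color))
        elif op == "text":
            _, (x, y), text, color, size = cmd
            font = _font(size * s)
            draw.text((x * s, y * s), str(text), fill=_rgb(color), font=font)
        else:  # pragma: no cover
            raise ValueError(f"unknown draw command {op!r}")

    if s > 1:
        img = img.resize((style.width, style.height), Image.BOX)
    return np.asarray(img, dtype=np.uint8).copy()


_FONT_CACHE: dict[int, ImageFont.ImageFont] = {}


def _font(size: int):
    # Pillow's bundled default font: deterministic across platforms.
    if size not in _FONT_CACHE:
        try:
            _FONT_CACHE[size] = ImageFont.load_default(size=size)
        except TypeError:  # very old Pillow
            _FONT_CACHE[size] = ImageFont.load_default()
    return _FONT_CACHE[size]


# ---------------------------------------------------------------------------
# frame-level API


def render_frame(
    metabolic_map: MetabolicMap,
    states: dict[str, NodeVisualState],
    vp: Viewport,
    style: RenderStyle,
    config: Optional[EncodingConfig] = None,
    index: int = 0,
    data_time: float = 0.0,
) -> Frame:
    """Rasterize one frame of the animation (deterministic)."""
    cmds = build_draw_commands(metabolic_map, states, vp, style, config)
    return Frame(image=rasterize(cmds, style), index=index, data_time=data_time)


def render_sbgn_frame(
    metabolic_map: MetabolicMap,
    states: dict[str, NodeVisualState],
    vp: Viewport,
    style: RenderStyle,
    config: Optional[EncodingConfig] = None,
    index: int = 0,
    data_time: float = 0.0,
) -> Frame:
    """As :func:`render_frame`, forcing the SBGN process-description style."""
    from dataclasses import replace

    return render_frame(
        metabolic_map, states, vp, replace(style, style="sbgn"), config, index, data_time
    )


def compose_legend(
    frame: Frame,
    config: EncodingConfig,
    data_time: float,
    style: Optional[RenderStyle] = None,
    show: bool = True,
    time_format: str = "t = {:g}",
) -> Frame:
    """Overlay a time stamp (and a colorbar for color encodings) onto a frame.

    The overlay sits in a fixed screen-space corner (top-left), independent
    of the camera.  ``show=False`` returns the frame unchanged.
    """
    if not show:
        return frame
    style = style or RenderStyle(width=frame.size[0], height=frame.size[1])
    img = frame.to_pil()
    draw = ImageDraw.Draw(img)
    pad = 6
    text = time_format.format(data_time)
    draw.text((pad, pad), text, fill=_rgb(style.label_color), font=_font(style.font_size))
    if config.mode in ("color", "size_color"):
        bar_w, bar_h = 80, 8
        y0 = pad + style.font_size + 6
        for i in range(bar_w):
            c = colormap_color(config.colormap, i / (bar_w - 1))
            draw.line([(pad + i, y0), (pad + i, y0 + bar_h)], fill=_rgb(c))
        draw.rectangle(
            [pad - 1, y0 - 1, pad + bar_w, y0 + bar_h + 1],
            outline=_rgb(style.outline_color),
            width=1,
        )
    return Frame(
        image=np.asarray(img, dtype=np.uint8).copy(),
        index=frame.index,
        data_time=data_time,
    )
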