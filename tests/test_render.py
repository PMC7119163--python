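"""Deterministic rasterization: fill-level glyphs, styles, camera transform."""
import numpy as np
import pytest

from gemvis.camera import Viewport
from gemvis.encoding import EncodingConfig, NodeVisualState
from gemvis.maps import Canvas, MapNode, MetabolicMap, ReactionEdge, Segment
from gemvis.render import (
    Frame,
    RenderStyle,
    build_draw_commands,
    compose_legend,
    draw_filled_node,
    rasterize,
    render_frame,
    render_sbgn_frame,
)

BG = (255, 255, 255)


def one_node_map(x=50.0, y=50.0):
    m = MetabolicMap(canvas=Canvas(width=100.0, height=100.0))
    m.add_node(MapNode("n1", "metabolite", x, y, bigg_id="atp_c"))
    return m


def chain_map():
    m = MetabolicMap(canvas=Canvas(width=200.0, height=100.0))
    m.add_node(MapNode("a", "metabolite", 40.0, 50.0, bigg_id="a_c"))
    m.add_node(MapNode("mid", "midmarker", 100.0, 50.0))
    m.add_node(MapNode("b", "metabolite", 160.0, 50.0, bigg_id="b_c"))
    m.add_reaction(ReactionEdge("r1", "R1", segments=[
        Segment("a", "mid"), Segment("mid", "b")]))
    return m


def filled_mask(image, background=BG):
    return np.any(image != np.array(background, dtype=np.uint8), axis=2)


class TestRenderFrame:
    STYLE = RenderStyle(width=100, height=100, supersampling=1)
    VP = Viewport(x=0.0, y=0.0, width=100.0, height=100.0)

    def test_empty_map_gives_uniform_background(self):
        m = MetabolicMap(canvas=Canvas(width=100.0, height=100.0))
        frame = render_frame(m, {}, self.VP, self.STYLE)
        assert not filled_mask(frame.image).any()

    def test_node_at_viewport_center_renders_centered(self):
        m = one_node_map(50.0, 50.0)
        states = {"n1": NodeVisualState(1.0, 10.0, (200.0, 30.0, 30.0))}
        frame = render_frame(m, states, self.VP, self.STYLE)
        ys, xs = np.nonzero(filled_mask(frame.image))
        assert abs(xs.mean() - 50.0) <= 1.0 and abs(ys.mean() - 50.0) <= 1.0

    def test_node_at_camera_corner_renders_at_origin(self):
        m = one_node_map(30.0, 40.0)
        vp = Viewport(x=30.0, y=40.0, width=100.0, height=100.0)
        states = {"n1": NodeVisualState(1.0, 8.0, (200.0, 30.0, 30.0))}
        frame = render_frame(m, states, vp, self.STYLE)
        ys, xs = np.nonzero(filled_mask(frame.image))
        # the glyph is centred at pixel (0, 0); its visible quarter touches it
        assert xs.min() == 0 and ys.min() == 0
        assert xs.max() <= 9 and ys.max() <= 9

    def test_identical_inputs_give_bit_identical_rasters(self):
        m = chain_map()
        style = RenderStyle(width=120, height=80, supersampling=2)
        vp = Viewport(x=0.0, y=0.0, width=200.0, height=100.0)
        states = {"a": NodeVisualState(0.4, 9.0, (10.0, 90.0, 200.0))}
        f1 = render_frame(m, states, vp, style)
        f2 = render_frame(m, states, vp, style)
        assert np.array_equal(f1.image, f2.image)

    def test_node_outside_viewport_contributes_no_pixels(self):
        m = one_node_map(500.0, 500.0)
        states = {"n1": NodeVisualState(1.0, 10.0, (200.0, 30.0, 30.0))}
        frame = render_frame(m, states, self.VP, self.STYLE)
        assert not filled_mask(frame.image).any()

    def test_unmeasured_nodes_get_gray_style(self):
        m = one_node_map()
        cfg = EncodingConfig()
        frame = render_frame(m, {}, self.VP, self.STYLE, cfg)
        mask = filled_mask(frame.image)
        assert mask.any()
        gray = np.array(cfg.unmeasured_color, dtype=np.uint8)
        # interior pixels carry the unmeasured gray
        assert (frame.image[mask] == gray).all(axis=1).any()


class TestFillLevel:
    def measure(self, fraction, radius_px=100, size=220):
        style = RenderStyle(width=size, height=size, supersampling=1)
        cmds = draw_filled_node(
            (size / 2, size / 2), radius_px, fraction,
            (200.0, 0.0, 0.0), (0.0, 0.0, 0.0), 1.0, (255.0, 255.0, 255.0),
        )
        image = rasterize(cmds, style)
        red = np.all(image == np.array([200, 0, 0], dtype=np.uint8), axis=2)
        return red

    @pytest.mark.parametrize("fraction", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_fill_height_linear_in_fraction(self, fraction):
        red = self.measure(fraction)
        if fraction == 0.0:
            assert red.sum() == 0
            return
        rows = np.nonzero(red.any(axis=1))[0]
        height = rows.max() - rows.min() + 1
        assert abs(height - fraction * 200) <= 2.0  # 200-px disk, +-1 px per edge

    def test_half_fill_is_half_the_disk_pixels(self):
        full = self.measure(1.0).sum()
        half = self.measure(0.5).sum()
        assert abs(half - full / 2) / (full / 2) <= 0.02

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            draw_filled_node((0, 0), 10, 1.5, (0, 0, 0), (0, 0, 0), 1, (255, 255, 255))


class TestStyles:
    VP = Viewport(x=0.0, y=0.0, width=200.0, height=100.0)

    def test_sbgn_adds_one_process_square_per_reaction(self):
        m = chain_map()
        sbgn = RenderStyle(style="sbgn", width=200, height=100)
        escher = RenderStyle(style="escher", width=200, height=100)
        cmds_sbgn = build_draw_commands(m, {}, self.VP, sbgn)
        cmds_escher = build_draw_commands(m, {}, self.VP, escher)
        squares = [c for c in cmds_sbgn if c[0] == "square"]
        assert len(squares) == len(m.reactions)
        assert not any(c[0] == "square" for c in cmds_escher)

    def test_one_circle_per_metabolite_in_both_styles(self):
        m = chain_map()
        for name in ("sbgn", "escher"):
            style = RenderStyle(style=name, width=200, height=100)
            cmds = build_draw_commands(m, {}, self.VP, style)
            outlines = [c for c in cmds if c[0] == "circle_outline"]
            assert len(outlines) == len(m.metabolite_nodes())

    def test_style_switch_keeps_node_pixel_positions(self):
        m = chain_map()
        centers = {}
        for name in ("sbgn", "escher"):
            style = RenderStyle(style=name, width=200, height=100)
            cmds = build_draw_commands(m, {}, self.VP, style)
            centers[name] = [c[1] for c in cmds if c[0] == "circle_outline"]
        assert centers["sbgn"] == centers["escher"]

    def test_process_square_sits_on_midmarker(self):
        m = chain_map()
        style = RenderStyle(style="sbgn", width=200, height=100)
        cmds = build_draw_commands(m, {}, self.VP, style)
        square = next(c for c in cmds if c[0] == "square")
        assert square[1] == (100.0, 50.0)  # viewport is the identity transform

    def test_z_order_edges_below_nodes(self):
        m = chain_map()
        style = RenderStyle(width=200, height=100)
        cmds = build_draw_commands(m, {}, self.VP, style)
        kinds = [c[0] for c in cmds]
        assert kinds.index("polyline") < kinds.index("circle_outline")


class TestLegend:
    def frame(self):
        image = np.full((60, 120, 3), 255, dtype=np.uint8)
        return Frame(image=image, index=3, data_time=2.5)

    def test_legend_off_returns_frame_unchanged(self):
        f = self.frame()
        out = compose_legend(f, EncodingConfig(), 2.5, show=False)
        assert out is f

    def test_timestamp_drawn(self):
        out = compose_legend(self.frame(), EncodingConfig(), 2.5)
        assert filled_mask(out.image).any()

    def test_colorbar_endpoints_match_colormap(self):
        cmap = ((0.0, 0.0, 255.0), (255.0, 0.0, 0.0))
        cfg = EncodingConfig(mode="color", colormap=cmap)
        out = compose_legend(self.frame(), cfg, 0.0)
        blue = np.all(out.image == np.array([0, 0, 255], dtype=np.uint8), axis=2)
        red = np.all(out.image == np.array([255, 0, 0], dtype=np.uint8), axis=2)
        assert blue.any() and red.any()
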