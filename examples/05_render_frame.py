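"""Rasterize one frame: fill-level glyphs in Escher and SBGN styles.

Renders a three-node map twice, once per style, and verifies the
deterministic-rendering contract (same inputs, bit-identical pixels).
"""
import numpy as np

from gemvis import NodeVisualState, RenderStyle, Viewport, render_frame
from gemvis.maps import Canvas, MapNode, MetabolicMap, ReactionEdge, Segment

m = MetabolicMap(canvas=Canvas(width=200.0, height=100.0))
m.add_node(MapNode("a", "metabolite", 40.0, 50.0, bigg_id="glc__D_c"))
m.add_node(MapNode("mid", "midmarker", 100.0, 50.0))
m.add_node(MapNode("b", "metabolite", 160.0, 50.0, bigg_id="g6p_c"))
m.add_reaction(ReactionEdge("r1", "HEX1",
                            segments=[Segment("a", "mid"), Segment("mid", "b")]))

states = {
    "a": NodeVisualState(fill_fraction=0.8, radius=10.0, color=(202.0, 33.0, 39.0)),
    "b": NodeVisualState(fill_fraction=0.3, radius=10.0, color=(202.0, 33.0, 39.0)),
}
vp = Viewport(x=0.0, y=0.0, width=200.0, height=100.0)

for style_name in ("escher", "sbgn"):
    style = RenderStyle(style=style_name, width=400, height=200)
    frame = render_frame(m, states, vp, style)
    again = render_frame(m, states, vp, style)
    non_bg = int(np.any(frame.image != 255, axis=2).sum())
    print(f"{style_name:>6}: {frame.size[0]}x{frame.size[1]} px, "
          f"{non_bg} drawn pixels, deterministic="
          f"{np.array_equal(frame.image, again.image)}")
# SBGN draws more pixels: it adds a process square on the reaction's
# midmarker.  Node circles sit at identical pixel positions in both styles.
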