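"""The four visual encodings of a metabolite pool size.

One normalized value can drive a node's fill level, its size, its color,
or size and color together.  Fill level is the default: fill *height* is
a length scale, which readers judge most accurately.
"""
from gemvis import EncodingConfig, encode

value, lo, hi = 6.5, 2.0, 8.0  # a pool measurement and its series bounds

for mode in ("fill", "size", "color", "size_color"):
    config = EncodingConfig(mode=mode, r_min=4.0, r_max=16.0)
    state = encode(value, lo, hi, config)
    print(f"{mode:>10}: fill={state.fill_fraction:.3f}  "
          f"radius={state.radius:5.2f}px  "
          f"color=({state.color[0]:.0f},{state.color[1]:.0f},{state.color[2]:.0f})")

# fill: the circle fills to 75% of its height (value sits 3/4 up the range)
# size: radius grows so that disk *area* is linear in the value
# color: position 0.75 along the two-stop colormap
# size_color: both channels at once, for absolute-abundance overviews
unmeasured = EncodingConfig().unmeasured_state()
print(f"unmeasured nodes are constant gray: color={unmeasured.color}, "
      f"measured={unmeasured.measured}")
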