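"""Parse a camera definition file and move the viewport along it.

The file format is a single record: first the zoom level, then a
tab-separated list of x/y pairs -- the viewport's top-left corners along
the way.  The camera traverses the corner polyline at constant speed
(arc-length parameterization) over the course of the animation.
"""
from gemvis.camera import parse_camera_text, viewport_at

camera_text = "2.0\t0\t0\t400\t0\t400\t200"
path = parse_camera_text(camera_text)
print(f"zoom {path.zoom} map-units/pixel, corners: {path.corners}")

dims = (320, 240)  # output pixels; viewport spans dims x zoom map units
for u in (0.0, 1 / 3, 2 / 3, 1.0):
    vp = viewport_at(path, u, dims)
    print(f"u={u:.3f}: top-left=({vp.x:6.1f},{vp.y:6.1f})  "
          f"size={vp.width:.0f}x{vp.height:.0f} map units")
# legs have lengths 400 and 200, so u=2/3 lands exactly on the middle
# corner (400, 0): equal u steps always cover equal map distance.
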