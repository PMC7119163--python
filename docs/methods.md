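# Methods

This note documents the models, conventions and numerical choices behind
`gemvis`, and what its synthetic test data do and do not demonstrate.

## The map model and its two serializations

A `MetabolicMap` is a node-link structure: metabolite glyphs and
mid/multimarker helper nodes with map-unit coordinates, reaction edges
whose drawn shape is an ordered list of segments (straight or cubic
Bezier, endpoints referencing node ids), a canvas, and free text labels.
It is the common in-memory form of two external formats:

- **Escher JSON** (schema family 1-0-x): a two-element array
  `[header, body]`; the header's schema string is sniffed and unknown
  major versions are rejected rather than guessed. Unrecognized keys on
  nodes/reactions are carried opaquely through round trips. The writer is
  canonical (sorted keys, fixed separators), so write–read–write cycles
  are bit-stable.
- **SBML Level 3 Version 1 + Layout v1**: one species glyph per
  metabolite node (bounding box centered on the node, default extent
  20 map units), one reaction glyph per edge with one
  species-reference glyph per segment carrying the segment's curve.
  Marker nodes get no glyph of their own — they are layout helpers, not
  species — so their coordinates live only inside reaction curves.

**Coordinate convention.** Screen orientation throughout: origin
top-left, y grows downward, exactly as Escher stores maps. SBML Layout
documents are written in the same orientation with no axis flip; both
renderers target screens, and flipping would break coordinate round
trips.

**Lossless conversion.** Layout v1 has no native slot for several Escher
attributes (BiGG ids, primary flags, label coordinates, marker identity
of segment endpoints, the canvas offset). These are stored in SBML
`<annotation>` elements under the `urn:gemvis:escher` namespace —
the standard extension point, so converted documents still pass
libSBML's full consistency check with zero errors and remain readable by
any SBML consumer. Foreign layout documents without these annotations
are read with a documented fallback: species glyph centers become
metabolite nodes and marker nodes are synthesized from curve endpoints
that coincide with no species glyph.

**Glyph ids.** Escher node ids are frequently bare integers, which are
not valid SBML SIds. Ids are sanitized deterministically: prefix
(`ng_`/`rg_`/`tg_`) + the original id with non-SId characters mapped to
`_`, plus a numeric disambiguator on collision; the original id is kept
in the annotation, making the mapping invertible.

**Merging.** `merge_layout_into_model` embeds a layout into a copy of a
GEM document (L3V1 required on both sides; FBC constructs are carried
through untouched and never interpreted). Species/reaction glyphs whose
BiGG id or reference matches a model id are linked; unmatched glyphs are
retained and reported, never dropped.

## Time-course interpolation

The data table is a rectangular CSV (either orientation, auto-detected
by finding the all-numeric axis; delimiter sniffed among `,`/`;`/tab;
gzip- or zip-wrapped input accepted). Times are sorted strictly
ascending; empty cells are missing values; duplicate metabolite rows are
an error. Time units are opaque labels — never converted.

Identifier matching is exact on BiGG ids first; an optional fallback
(default on) strips a trailing compartment suffix (`_c`, `_e`, `_m`, …)
from either side and retries, so `glc__D` in the data finds `glc__D_c`
on the map. An empty match set is a warning, not an error.

**Spline family.** Natural cubic interpolating splines (scipy's
`CubicSpline` with natural boundary), the minimal smooth interpolant and
reproducible from textbooks; the test suite checks it against an
independent dense tridiagonal solve of the classic second-derivative
system. With exactly 3 (2) non-missing knots the fit degrades to the
unique interpolating quadratic (linear); a single point is held constant
with a warning; all-missing series are excluded. Monotone PCHIP
interpolation is available as an overshoot-free option, and plain linear
as a third.

- *Missing values* are dropped per series before fitting, so each series
  keeps its own knot set; nothing is imputed.
- *Non-negativity*: concentrations cannot be negative, but natural
  splines can undershoot between knots. Values are clamped at a floor
  (default 0) **after** evaluation rather than constraining the fit —
  simple, predictable, and it leaves knot values untouched.
- *No extrapolation*: animation time maps affinely onto
  `[t_first, t_last]`; queries outside return the boundary values.
- *Frame grid*: `n = round(duration_s × fps)` frames, frame *i* at data
  time `t_first + i/(n−1) · (t_last − t_first)`, so the first and last
  frames carry the measured boundary values exactly.

A note on accuracy: a natural spline reproduces a cubic-polynomial
generator only away from the boundary (the natural end condition
perturbs the outermost intervals; the perturbation decays geometrically
inward). The recovery check therefore samples 25 knots and asserts
`≤ 1e-6` relative error on the middle third.

## Visual encoding

A value is first normalized to [0, 1] against bounds chosen by the
normalization policy, then mapped to a `NodeVisualState`:

| mode | varies | constant |
|---|---|---|
| `fill` (default) | fill fraction | radius `r_base`, color |
| `size` | radius in `[r_min, r_max]` | fill = 1, color |
| `color` | colormap position | fill = 1, radius |
| `size_color` | radius and color | fill = 1 |

Defaults: `r_min = 4`, `r_max = 16`, `r_base = 10` pixels; a two-stop
sequential colormap (light blue-gray → saturated red).

- *Normalization* defaults to per-metabolite min/max over the whole
  animation, so every node visits fill 0 and 1 — a relative-pool-size
  view. `global` and `fixed (lo, hi)` bounds serve absolute-abundance
  comparisons across metabolites. Bounds are computed once over the
  whole series and out-of-range values clip, so frames stay mutually
  comparable; `log10(1+v)` pre-scaling is an off-by-default flag.
- *Size law* defaults to area-linear (`r = sqrt(r_min² + f·(r_max² −
  r_min²))`) so perceived disk area tracks the value; radius-linear is
  available.
- *Degenerate range* (constant series): normalize returns 0.5 rather
  than dividing by zero.
- *Unmeasured nodes* always receive one constant gray state, never a
  data-driven one.

## Camera

The camera file is one logical record: the first value is the zoom
level, then a tab-separated list of x/y pairs — the viewport's top-left
corners along the way (commas and newlines tolerated; tabs canonical).
Zoom is interpreted as **map units per output pixel**, constant along
the path (the format carries a single leading value), so the viewport
spans `pixel dims × zoom` map units. The camera's progress parameter
equals normalized animation time and the corner polyline is traversed by
cumulative arc length, giving constant on-screen panning speed; linear
per leg by default, Catmull-Rom smoothing opt-in. Viewports may leave
the canvas (`free`, default — the file's corners are authoritative) or
be minimally translated back (`clamp`), centering when the viewport is
larger than the canvas.

## Rendering

Rendering is split into an inspectable ordered command stream (z-order:
edges < nodes < labels < legend) and a Pillow rasterizer. Anti-aliasing
is fixed integer supersampling (default 2×) followed by box
downsampling — no renderer- or platform-dependent AA — so identical
inputs yield bit-identical rasters. Labels use Pillow's bundled default
font for the same reason. Glyphs wholly outside the viewport emit no
commands.

**Fill-level glyphs** fill the circle bottom-up to height
`fraction × diameter`: the filled region is the circular segment below
the horizontal chord at that height. Fill *height*, not fill area, is
linear in the fraction — the length-scale choice, since lengths are the
visual channel people judge most accurately. The geometry is tested by
pixel counting on a 200-px disk (height within 1 px per edge; half fill
covers half the disk pixels within 2%).

Two styles: `escher` (plain curved edges; markers are invisible joints)
and `sbgn` (process-description subset: simple-chemical circles plus a
small process square on each reaction's midmarker; no clone markers or
compartment glyphs). Switching style never moves a node's pixel
position. An optional legend overlays a time stamp and, for color
encodings, a colorbar in a fixed screen-space corner independent of the
camera.

## Export

Pipeline: read map → (merge model) → read data → match → interpolate →
sample frames → encode → camera → render → mux, with
`round(duration × fps)` frames and an exit report carrying the match
summary, the frame count and a SHA-256 digest over all pre-mux frame
buffers (the determinism handle: two runs of one job digest
identically).

Container support is tiered by what it can guarantee:

- **PNG frame sequence** and **multi-page TIFF** (deflate-compressed,
  fps recorded in the image description): lossless, frame-exact,
  decodable with Pillow alone — the reference path for testing.
- **Animated GIF**: always available, but the format palette-quantizes
  colors and its writer coalesces consecutive *identical* frames, so
  frame counts are only exact for non-constant content.
- **MP4/AVI/MOV/MPG/WMV/FLV** via imageio's ffmpeg backend when one is
  installed; without it the job fails with an error naming the missing
  capability instead of silently degrading.

The legend defaults to off in animation jobs so that constant input data
yields bit-identical frames.

## Synthetic data generator

`gemvis.fixtures` generates the three pipeline inputs with known ground
truth: a connected serpentine-grid chain map (one midmarker per
reaction, mild Bezier bends so curve handling is exercised), a matching
SBML L3V1 model whose species ids equal the map's BiGG ids
(`met{j}_c`, one cytosol compartment), and per-metabolite time series
from named dynamics — constant, linear, exponential decay, logistic
rise, sinusoid, the qualitative shapes of metabolite pools during blood
storage — plus seeded Gaussian noise. Defaults are 8 time points over a
span of 10 (the cadence of a ten-day storage experiment sampled eight
times), amplitudes of order 1–10 in arbitrary concentration units, and
noise off unless requested. The noise-free generating functions are
returned alongside the CSV so tests can separate knot fidelity (the
interpolant must reproduce the *noisy* measurements) from generator
recovery. All randomness flows through an explicit seed.

What the generator does **not** emulate: genome-scale map sizes
(thousands of glyphs), realistic reaction stoichiometry or kinetics,
heteroscedastic measurement error, missing-at-random patterns typical of
metabolomics platforms, or identifier mismatch noise beyond compartment
suffixes. Passing tests therefore demonstrate the correctness of the
conversion/interpolation/encoding/rendering machinery, not robustness
to the full messiness of real laboratory data.

## Problem sizes in tests

The test suite and the acceptance script run small, fixed problem
sizes chosen to exercise every code path while keeping the whole suite
fast: maps of 3–50 nodes (100 seeded random maps for the round-trip
check), 8-knot series (25 knots for the cubic-recovery check), 200-px
disks for fill geometry, and 320×240, 2-second, 10-fps end-to-end jobs.

## Known limitations

- Only SBML Level 3 Version 1 is supported; the Render extension is not
  emitted or read.
- Zoom is constant along a camera path (the file format carries a single
  value); variable zoom, rotation and easing are out of scope.
- The SBGN subset covers process-description circles/squares/arcs only.
- Reaction fluxes on edges are not encoded; the encodings cover node
  pool sizes.
- GIF output inherits the format's 256-color palette and
  duplicate-frame coalescing.
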