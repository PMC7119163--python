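"""In-memory representation of a metabolic network map.

A :class:`MetabolicMap` is the common denominator of the two interchange
formats this package speaks — Escher's node/reaction JSON documents and the
SBML Level 3 Layout extension.  It is a node-link structure: metabolite and
marker glyphs with map-unit coordinates, reaction edges whose drawn shape is
an ordered list of (optionally cubic-Bezier) segments between node ids, a
drawing canvas, and free-floating text labels.

Coordinate convention: screen orientation throughout — the origin is the
top-left corner of the canvas and y grows *downward*, exactly as Escher
stores its maps.  SBML Layout documents written by this package use the same
orientation (no axis flip), so coordinates survive round trips unchanged.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "Canvas",
    "MapNode",
    "Segment",
    "ReactionEdge",
    "TextLabel",
    "MetabolicMap",
    "MapIntegrityError",
    "NodeKind",
]


class MapIntegrityError(ValueError):
    """A structural invariant of the map is violated (dangling ids, ...)."""


#: Allowed node kinds.  ``metabolite`` nodes are chemical species;
#: ``midmarker``/``multimarker`` nodes are layout helpers marking the middle
#: and branch points of a reaction's drawn curve.
NodeKind = ("metabolite", "midmarker", "multimarker")


@dataclass
class Canvas:
    """Drawing extent of the map, in map units (top-left origin)."""

    x: float = 0.0
    y: float = 0.0
    width: float = 1000.0
    height: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"canvas width/height must be positive, got {self.width} x {self.height}"
            )


@dataclass
class MapNode:
    """One glyph: a metabolite circle or a reaction mid/multimarker."""

    node_id: str
    kind: str  # one of NodeKind
    x: float
    y: float
    bigg_id: str = ""
    display_name: str = ""
    is_primary: bool = False
    label_x: Optional[float] = None
    label_y: Optional[float] = None
    extras: dict = field(default_factory=dict)  # unknown Escher keys, kept opaquely

    def __post_init__(self) -> None:
        if self.kind not in NodeKind:
            raise ValueError(f"unknown node kind {self.kind!r} for node {self.node_id!r}")
        if self.kind == "metabolite" and not self.bigg_id:
            raise MapIntegrityError(f"metabolite node {self.node_id!r} has empty bigg_id")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise MapIntegrityError(f"node {self.node_id!r} has non-finite coordinates")


@dataclass
class Segment:
    """One drawn piece of a reaction edge between two node ids.

    ``b1``/``b2`` are the interior control points of a cubic Bezier; a
    straight line when both are absent.  Exactly one of the two being set is
    invalid.
    """

    from_node_id: str
    to_node_id: str
    b1: Optional[tuple[float, float]] = None
    b2: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if (self.b1 is None) != (self.b2 is None):
            raise MapIntegrityError(
                f"segment {self.from_node_id!r}->{self.to_node_id!r}: "
                "b1 and b2 must both be present or both absent"
            )

    @property
    def is_bezier(self) -> bool:
        return self.b1 is not None


@dataclass
class ReactionEdge:
    """One reaction: identity, label position, and its drawn segments."""

    reaction_id: str
    bigg_id: str
    label_x: float = 0.0
    label_y: float = 0.0
    reversibility: bool = False
    segments: list[Segment] = field(default_factory=list)
    extras: dict = field(default_factory=dict)


@dataclass
class TextLabel:
    text: str
    x: float
    y: float


@dataclass
class MetabolicMap:
    """A validated node-link pathway map."""

    map_name: str = ""
    schema_version: str = "1-0-4"
    canvas: Canvas = field(default_factory=Canvas)
    nodes: dict[str, MapNode] = field(default_factory=dict)
    reactions: dict[str, ReactionEdge] = field(default_factory=dict)
    text_labels: list[TextLabel] = field(default_factory=list)

    # -- construction helpers -------------------------------------------------

    def add_node(self, node: MapNode) -> None:
        if node.node_id in self.nodes:
            raise MapIntegrityError(f"duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node

    def add_reaction(self, edge: ReactionEdge) -> None:
        if edge.reaction_id in self.reactions:
            raise MapIntegrityError(f"duplicate reaction id {edge.reaction_id!r}")
        self.reactions[edge.reaction_id] = edge

    # -- queries --------------------------------------------------------------

    def metabolite_nodes(self) -> list[MapNode]:
        return [n for n in self.nodes.values() if n.kind == "metabolite"]

    def marker_nodes(self) -> list[MapNode]:
        return [n for n in self.nodes.values() if n.kind != "metabolite"]

    def bigg_ids(self) -> set[str]:
        return {n.bigg_id for n in self.metabolite_nodes()}

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity; raise :class:`MapIntegrityError`."""
        for rid, edge in self.reactions.items():
            if not edge.segments:
                raise MapIntegrityError(f"reaction {rid!r} has no segments")
            for k, seg in enumerate(edge.segments):
                for endpoint in (seg.from_node_id, seg.to_node_id):
                    if endpoint not in self.nodes:
                        raise MapIntegrityError(
                            f"reaction {rid!r} segment {k} references "
                            f"unknown node {endpoint!r}"
                        )

    def equal_to(self, other: "MetabolicMap", tol: float = 1e-9) -> bool:
        """Structural equality with a coordinate tolerance (for round trips)."""
        return not self.diff(other, tol)

    def diff(self, other: "MetabolicMap", tol: float = 1e-9) -> list[str]:
        """Human-readable list of differences; empty when maps agree."""
        out: list[str] = []

        def close(a: float, b: float) -> bool:
            return abs(a - b) <= tol

        if set(self.nodes) != set(other.nodes):
            out.append(
                f"node id sets differ: {sorted(set(self.nodes) ^ set(other.nodes))[:5]}"
            )
            return out
        for nid, a in self.nodes.items():
            b = other.nodes[nid]
            if a.kind != b.kind:
                out.append(f"node {nid}: kind {a.kind} != {b.kind}")
            if not (close(a.x, b.x) and close(a.y, b.y)):
                out.append(f"node {nid}: center ({a.x},{a.y}) != ({b.x},{b.y})")
            if a.kind == "metabolite":
                if a.bigg_id != b.bigg_id:
                    out.append(f"node {nid}: bigg_id {a.bigg_id} != {b.bigg_id}")
                if a.is_primary != b.is_primary:
                    out.append(f"node {nid}: is_primary differs")
        if set(self.reactions) != set(other.reactions):
            out.append("reaction id sets differ")
            return out
        for rid, ra in self.reactions.items():
            rb = other.reactions[rid]
            if ra.bigg_id != rb.bigg_id or ra.reversibility != rb.reversibility:
                out.append(f"reaction {rid}: identity differs")
            if len(ra.segments) != len(rb.segments):
                out.append(f"reaction {rid}: segment counts differ")
                continue
            for k, (sa, sb) in enumerate(zip(ra.segments, rb.segments)):
                if (sa.from_node_id, sa.to_node_id) != (sb.from_node_id, sb.to_node_id):
                    out.append(f"reaction {rid} segment {k}: endpoints differ")
                if sa.is_bezier != sb.is_bezier:
                    out.append(f"reaction {rid} segment {k}: bezier-ness differs")
                elif sa.is_bezier:
                    for pa, pb in ((sa.b1, sb.b1), (sa.b2, sb.b2)):
                        if not (close(pa[0], pb[0]) and close(pa[1], pb[1])):
                            out.append(f"reaction {rid} segment {k}: control points differ")
        return out


def bezier_point(
    p0: tuple[float, float],
    p1: Optional[tuple[float, float]],
    p2: Optional[tuple[float, float]],
    p3: tuple[float, float],
    t: float,
) -> tuple[float, float]:
    """Point on a cubic Bezier (or straight line when controls are absent)."""
    if p1 is None:
        return (p0[0] + (p3[0] - p0[0]) * t, p0[1] + (p3[1] - p0[1]) * t)
    u = 1.0 - t
    bx = u**3 * p0[0] + 3 * u**2 * t * p1[0] + 3 * u * t**2 * p2[0] + t**3 * p3[0]
    by = u**3 * p0[1] + 3 * u**2 * t * p1[1] + 3 * u * t**2 * p2[1] + t**3 * p3[1]
    return (bx, by)
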