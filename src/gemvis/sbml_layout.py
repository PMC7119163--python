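"""Convert pathway maps between Escher JSON and the SBML Layout extension,
and merge a layout document into a genome-scale model.

Target format: SBML Level 3 Version 1 with Layout extension version 1.  The
flux-balance-constraints (FBC) package is tolerated on input models and
carried through untouched, never interpreted.

Mapping rules
-------------
* Each metabolite node becomes one species glyph whose bounding box is
  centred on the node (default extent 20 map units).  Mid/multimarker nodes
  get no glyph of their own: their coordinates live only inside reaction
  curves, as they are layout helpers rather than species.
* Each reaction edge becomes one reaction glyph; each drawn segment becomes
  one species-reference glyph carrying the segment's curve (a cubic Bezier
  or a straight line).
* Glyph ids are deterministic SIds: prefix (``ng_``/``rg_``/``tg_``) +
  the original id with non-SId characters mapped to ``_``, plus a numeric
  disambiguator on collision.  The original id is kept in the glyph ``name``
  so the mapping is invertible.
* Escher attributes with no native slot in Layout v1 (BiGG ids, primary
  flags, label coordinates, marker identities of segment endpoints) are
  stored in SBML annotation elements under the ``urn:gemvis:escher``
  namespace, which keeps documents valid for any SBML consumer while making
  the conversion lossless for this package.

Coordinates are written in screen orientation (y down, origin top-left),
identical to the Escher convention — no axis flip, so round trips preserve
coordinates exactly.
"""
from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Optional, Union

import libsbml

from .escher import GZIP_MAGIC
from .maps import (
    Canvas,
    MapNode,
    MetabolicMap,
    ReactionEdge,
    Segment,
    TextLabel,
)

__all__ = [
    "escher_to_sbml_layout",
    "read_sbml_layout",
    "merge_layout_into_model",
    "write_sbml",
    "read_sbml",
    "validate_sbml",
    "GlyphMatchReport",
    "NoLayoutError",
    "SBMLReadError",
    "SIdCollisionError",
]

NS = "urn:gemvis:escher"
DEFAULT_SPECIES_EXTENT = 20.0
_LAYOUT_URI = "http://www.sbml.org/sbml/level3/version1/layout/version1"


class NoLayoutError(ValueError):
    """The SBML document parsed fine but holds no layout."""


class SBMLReadError(ValueError):
    """libSBML reported read/consistency errors; carries the severity list."""

    def __init__(self, message: str, error_log: list[str]):
        super().__init__(message + "\n" + "\n".join(error_log))
        self.error_log = error_log


class SIdCollisionError(ValueError):
    """Distinct original ids sanitised to the same SId."""


@dataclass
class GlyphMatchReport:
    """Outcome of linking layout glyphs against a model's ids."""

    matched_species: list[str] = field(default_factory=list)
    matched_reactions: list[str] = field(default_factory=list)
    unmatched_species: list[str] = field(default_factory=list)
    unmatched_reactions: list[str] = field(default_factory=list)

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched_species) + len(self.unmatched_reactions)

    def summary(self) -> str:
        return (
            f"linked {len(self.matched_species)} species glyphs and "
            f"{len(self.matched_reactions)} reaction glyphs; "
            f"{self.n_unmatched} glyph(s) unmatched"
        )


# ---------------------------------------------------------------------------
# SId sanitisation

_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def sanitize_sid(original: str, prefix: str, taken: set[str]) -> str:
    """Deterministic valid-SId form of ``original``; unique within ``taken``."""
    base = prefix + _SID_BAD.sub("_", original)
    if not re.match(r"^[A-Za-z_]", base):
        base = "_" + base
    sid = base
    k = 1
    while sid in taken:
        k += 1
        sid = f"{base}_{k}"
    taken.add(sid)
    return sid


# ---------------------------------------------------------------------------
# annotation plumbing


def _set_annotation(sbase, tag: str, attrs: dict) -> None:
    attr_s = "".join(f' {k}="{_xml_escape(str(v))}"' for k, v in attrs.items() if v is not None)
    xml = f'<gv:{tag} xmlns:gv="{NS}"{attr_s}/>'
    sbase.appendAnnotation(xml)


def _xml_escape(s: str) -> str:
    return (
        s.replace("&", "&amp;")
        .replace("<", "&lt;")
        .replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _get_annotation(sbase, tag: str) -> Optional[dict]:
    ann = sbase.getAnnotation()
    if ann is None:
        return None
    for i in range(ann.getNumChildren()):
        child = ann.getChild(i)
        if child.getName() == tag and child.getURI() == NS:
            attrs = child.getAttributes()
            return {attrs.getName(j): attrs.getValue(j) for j in range(attrs.getLength())}
    return None


# ---------------------------------------------------------------------------
# Escher -> SBML Layout


def _segment_points(m: MetabolicMap, segments) -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = []
    for seg in segments:
        a, b = m.nodes[seg.from_node_id], m.nodes[seg.to_node_id]
        pts.extend([(a.x, a.y), (b.x, b.y)])
        if seg.is_bezier:
            pts.extend([seg.b1, seg.b2])
    return pts


def _extent_bbox(layoutns, bb_id: str, pts: list[tuple[float, float]]):
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    # strictly positive extent keeps the bounding box schema-valid
    w = max(max(xs) - min(xs), 1e-6)
    h = max(max(ys) - min(ys), 1e-6)
    return libsbml.BoundingBox(layoutns, bb_id, min(xs), min(ys), w, h)


def escher_to_sbml_layout(
    metabolic_map: MetabolicMap,
    model_doc: Optional[libsbml.SBMLDocument] = None,
    species_extent: float = DEFAULT_SPECIES_EXTENT,
) -> libsbml.SBMLDocument:
    """Convert a map to an SBML L3V1 document with one Layout v1 layout.

    When ``model_doc`` is given, the layout is embedded into a *copy* of the
    model document and glyphs are linked to its species/reactions wherever
    the map's BiGG id matches a model id; otherwise the document carries a
    minimal empty model plus the layout (glyph identity then lives entirely
    in the annotations).
    """
    metabolic_map.validate()

    if model_doc is not None:
        doc = model_doc.clone()
        doc.enablePackage(_LAYOUT_URI, "layout", True)
        doc.setPackageRequired("layout", False)
        model = doc.getModel()
        if model is None:
            raise ValueError("model document has no model element")
    else:
        sbmlns = libsbml.SBMLNamespaces(3, 1, "layout", 1)
        doc = libsbml.SBMLDocument(sbmlns)
        doc.setPackageRequired("layout", False)
        model = doc.createModel()
        model.setId("gemvis_layout_model")

    layoutns = libsbml.LayoutPkgNamespaces(3, 1, 1)
    lplug = model.getPlugin("layout")
    layout = lplug.createLayout()
    layout.setId("layout_1")
    layout.setName(metabolic_map.map_name or "layout")
    dims = libsbml.Dimensions(
        layoutns, metabolic_map.canvas.width, metabolic_map.canvas.height
    )
    layout.setDimensions(dims)
    _set_annotation(
        layout,
        "canvas",
        {
            "x": repr(metabolic_map.canvas.x),
            "y": repr(metabolic_map.canvas.y),
            "schemaVersion": metabolic_map.schema_version,
        },
    )

    model_species = {model.getSpecies(i).getId() for i in range(model.getNumSpecies())}
    model_reactions = {model.getReaction(i).getId() for i in range(model.getNumReactions())}

    taken: set[str] = set()
    sid_of_node: dict[str, str] = {}
    # species glyphs for metabolite nodes only
    for node in metabolic_map.nodes.values():
        if node.kind != "metabolite":
            continue
        sid = sanitize_sid(node.node_id, "ng_", taken)
        if sid in sid_of_node.values():  # pragma: no cover - sanitize_sid guarantees
            raise SIdCollisionError(sid)
        sid_of_node[node.node_id] = sid
        sg = layout.createSpeciesGlyph()
        sg.setId(sid)
        if node.bigg_id in model_species:
            sg.setSpeciesId(node.bigg_id)
        bb = libsbml.BoundingBox(
            layoutns,
            sid + "_bb",
            node.x - species_extent / 2.0,
            node.y - species_extent / 2.0,
            species_extent,
            species_extent,
        )
        sg.setBoundingBox(bb)
        _set_annotation(
            sg,
            "node",
            {
                "originalId": node.node_id,
                "biggId": node.bigg_id,
                "displayName": node.display_name,
                "isPrimary": "true" if node.is_primary else "false",
                "labelX": None if node.label_x is None else repr(node.label_x),
                "labelY": None if node.label_y is None else repr(node.label_y),
            },
        )

    for edge in metabolic_map.reactions.values():
        rgid = sanitize_sid(edge.reaction_id, "rg_", taken)
        rg = layout.createReactionGlyph()
        rg.setId(rgid)
        if edge.bigg_id in model_reactions:
            rg.setReactionId(edge.bigg_id)
        rg.setBoundingBox(
            _extent_bbox(layoutns, rgid + "_bb", _segment_points(metabolic_map, edge.segments))
        )
        _set_annotation(
            rg,
            "reaction",
            {
                "originalId": edge.reaction_id,
                "biggId": edge.bigg_id,
                "labelX": repr(edge.label_x),
                "labelY": repr(edge.label_y),
                "reversibility": "true" if edge.reversibility else "false",
            },
        )
        for k, seg in enumerate(edge.segments):
            srg = rg.createSpeciesReferenceGlyph()
            srg.setId(f"{rgid}_seg_{k}")
            from_node = metabolic_map.nodes[seg.from_node_id]
            to_node = metabolic_map.nodes[seg.to_node_id]
            srg.setBoundingBox(
                _extent_bbox(
                    layoutns,
                    f"{rgid}_seg_{k}_bb",
                    _segment_points(metabolic_map, [seg]),
                )
            )
            for endpoint in (from_node, to_node):
                if endpoint.kind == "metabolite":
                    srg.setSpeciesGlyphId(sid_of_node[endpoint.node_id])
                    break
            curve = srg.getCurve()
            if seg.is_bezier:
                cs = curve.createCubicBezier()
                cs.setBasePoint1(libsbml.Point(layoutns, seg.b1[0], seg.b1[1]))
                cs.setBasePoint2(libsbml.Point(layoutns, seg.b2[0], seg.b2[1]))
            else:
                cs = curve.createLineSegment()
            cs.setStart(libsbml.Point(layoutns, from_node.x, from_node.y))
            cs.setEnd(libsbml.Point(layoutns, to_node.x, to_node.y))
            _set_annotation(
                srg,
                "segment",
                {
                    "fromId": seg.from_node_id,
                    "fromKind": from_node.kind,
                    "toId": seg.to_node_id,
                    "toKind": to_node.kind,
                },
            )

    for i, label in enumerate(metabolic_map.text_labels):
        tgid = sanitize_sid(str(i), "tg_", taken)
        tg = layout.createTextGlyph()
        tg.setId(tgid)
        tg.setText(label.text)
        bb = libsbml.BoundingBox(layoutns, tgid + "_bb", label.x, label.y, 1.0, 1.0)
        tg.setBoundingBox(bb)

    return doc


# ---------------------------------------------------------------------------
# SBML -> Escher


def read_sbml(source: Union[str, Path, bytes, BinaryIO]) -> libsbml.SBMLDocument:
    """Read an SBML document from a path/stream/bytes, gunzipping if needed."""
    if isinstance(source, (str, Path)):
        raw = Path(source).read_bytes()
    elif isinstance(source, bytes):
        raw = source
    else:
        raw = source.read()
    if raw[:2] == GZIP_MAGIC:
        raw = gzip.decompress(raw)
    doc = libsbml.readSBMLFromString(raw.decode("utf-8"))
    errors = _severe_errors(doc)
    if errors:
        raise SBMLReadError("SBML document failed to parse", errors)
    return doc


def _severe_errors(doc: libsbml.SBMLDocument) -> list[str]:
    out = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            out.append(f"[{err.getSeverityAsString()}] line {err.getLine()}: {err.getMessage()}")
    return out


def validate_sbml(doc: libsbml.SBMLDocument) -> list[str]:
    """Run libSBML's full consistency check; return severe errors (empty = valid)."""
    doc.checkConsistency()
    return _severe_errors(doc)


def read_sbml_layout(
    source: Union[str, Path, bytes, BinaryIO, libsbml.SBMLDocument],
) -> tuple[MetabolicMap, libsbml.SBMLDocument]:
    """Read the first layout of an SBML L3V1 document into a MetabolicMap.

    Documents written by :func:`escher_to_sbml_layout` round-trip exactly
    (ids, kinds, coordinates).  Foreign layout documents are read with a
    fallback: marker nodes are synthesised from curve endpoints that do not
    coincide with any species-glyph centre.

    Raises :class:`NoLayoutError` when the document has no layout — a
    distinct condition from a parse failure (:class:`SBMLReadError`).
    """
    doc = source if isinstance(source, libsbml.SBMLDocument) else read_sbml(source)
    model = doc.getModel()
    lplug = model.getPlugin("layout") if model is not None else None
    if lplug is None or lplug.getNumLayouts() == 0:
        raise NoLayoutError("SBML document contains no layout")
    layout = lplug.getLayout(0)

    canvas_attrs = _get_annotation(layout, "canvas") or {}
    dims = layout.getDimensions()
    canvas = Canvas(
        x=float(canvas_attrs.get("x", 0.0)),
        y=float(canvas_attrs.get("y", 0.0)),
        width=dims.getWidth() if dims is not None and dims.getWidth() > 0 else 1000.0,
        height=dims.getHeight() if dims is not None and dims.getHeight() > 0 else 1000.0,
    )
    m = MetabolicMap(
        map_name=layout.getName() or "",
        schema_version=canvas_attrs.get("schemaVersion", "1-0-4"),
        canvas=canvas,
    )

    # species glyphs -> metabolite nodes
    for i in range(layout.getNumSpeciesGlyphs()):
        sg = layout.getSpeciesGlyph(i)
        bb = sg.getBoundingBox()
        cx = bb.getPosition().getXOffset() + bb.getDimensions().getWidth() / 2.0
        cy = bb.getPosition().getYOffset() + bb.getDimensions().getHeight() / 2.0
        attrs = _get_annotation(sg, "node") or {}
        node_id = attrs.get("originalId") or sg.getName() or sg.getId()
        bigg = attrs.get("biggId") or sg.getSpeciesId() or node_id
        m.add_node(
            MapNode(
                node_id=node_id,
                kind="metabolite",
                x=cx,
                y=cy,
                bigg_id=bigg,
                display_name=attrs.get("displayName", ""),
                is_primary=attrs.get("isPrimary") == "true",
                label_x=_opt(attrs.get("labelX")),
                label_y=_opt(attrs.get("labelY")),
            )
        )

    # reaction glyphs -> edges; marker nodes recovered from segment annotations
    # (or synthesised from curve endpoints for foreign documents)
    synth_counter = 0
    center_index = {(round(n.x, 6), round(n.y, 6)): n.node_id for n in m.nodes.values()}

    def node_at(x: float, y: float, nid: Optional[str], kind: Optional[str]) -> str:
        nonlocal synth_counter
        if nid is not None:
            if nid not in m.nodes:
                m.add_node(MapNode(node_id=nid, kind=kind or "midmarker", x=x, y=y))
                center_index[(round(x, 6), round(y, 6))] = nid
            return nid
        key = (round(x, 6), round(y, 6))
        if key in center_index:
            return center_index[key]
        synth_counter += 1
        sid = f"marker_{synth_counter}"
        m.add_node(MapNode(node_id=sid, kind="midmarker", x=x, y=y))
        center_index[key] = sid
        return sid

    for i in range(layout.getNumReactionGlyphs()):
        rg = layout.getReactionGlyph(i)
        attrs = _get_annotation(rg, "reaction") or {}
        rid = attrs.get("originalId") or rg.getName() or rg.getId()
        segments: list[Segment] = []
        for j in range(rg.getNumSpeciesReferenceGlyphs()):
            srg = rg.getSpeciesReferenceGlyph(j)
            sattrs = _get_annotation(srg, "segment") or {}
            curve = srg.getCurve()
            for k in range(curve.getNumCurveSegments()):
                cs = curve.getCurveSegment(k)
                sx, sy = cs.getStart().getXOffset(), cs.getStart().getYOffset()
                ex, ey = cs.getEnd().getXOffset(), cs.getEnd().getYOffset()
                from_id = node_at(sx, sy, sattrs.get("fromId"), sattrs.get("fromKind"))
                to_id = node_at(ex, ey, sattrs.get("toId"), sattrs.get("toKind"))
                b1 = b2 = None
                if cs.getTypeCode() == libsbml.SBML_LAYOUT_CUBICBEZIER:
                    p1, p2 = cs.getBasePoint1(), cs.getBasePoint2()
                    b1 = (p1.getXOffset(), p1.getYOffset())
                    b2 = (p2.getXOffset(), p2.getYOffset())
                segments.append(Segment(from_id, to_id, b1, b2))
        if not segments and rg.isSetCurve():  # foreign docs: curve on the glyph itself
            curve = rg.getCurve()
            for k in range(curve.getNumCurveSegments()):
                cs = curve.getCurveSegment(k)
                from_id = node_at(cs.getStart().getXOffset(), cs.getStart().getYOffset(), None, None)
                to_id = node_at(cs.getEnd().getXOffset(), cs.getEnd().getYOffset(), None, None)
                segments.append(Segment(from_id, to_id))
        m.add_reaction(
            ReactionEdge(
                reaction_id=rid,
                bigg_id=attrs.get("biggId", rg.getReactionId() or rid),
                label_x=float(attrs.get("labelX", 0.0)),
                label_y=float(attrs.get("labelY", 0.0)),
                reversibility=attrs.get("reversibility") == "true",
                segments=segments,
            )
        )

    for i in range(layout.getNumTextGlyphs()):
        tg = layout.getTextGlyph(i)
        if not tg.isSetText():
            continue
        bb = tg.getBoundingBox()
        m.text_labels.append(
            TextLabel(
                text=tg.getText(),
                x=bb.getPosition().getXOffset(),
                y=bb.getPosition().getYOffset(),
            )
        )

    m.validate()
    return m, doc


def _opt(v):
    return None if v is None else float(v)


# ---------------------------------------------------------------------------
# merge


def merge_layout_into_model(
    model_doc: libsbml.SBMLDocument, layout_doc: libsbml.SBMLDocument
) -> tuple[libsbml.SBMLDocument, GlyphMatchReport]:
    """Embed the layout(s) of ``layout_doc`` into a copy of ``model_doc``.

    The merged document keeps the model's full species/reaction lists (FBC
    attributes untouched) and gains the layout.  Species and reaction glyphs
    whose BiGG id (annotation) or name matches a model id are linked via the
    glyph's ``species``/``reaction`` attribute; unmatched glyphs are retained
    and listed in the returned :class:`GlyphMatchReport`.
    """
    for name, doc in (("model", model_doc), ("layout", layout_doc)):
        if doc.getLevel() != 3 or doc.getVersion() != 1:
            raise ValueError(
                f"{name} document is SBML L{doc.getLevel()}V{doc.getVersion()}; "
                "Level 3 Version 1 is required"
            )
    src_model = layout_doc.getModel()
    src_plug = src_model.getPlugin("layout") if src_model is not None else None
    if src_plug is None or src_plug.getNumLayouts() == 0:
        raise NoLayoutError("layout document contains no layout")

    merged = model_doc.clone()
    merged.enablePackage(_LAYOUT_URI, "layout", True)
    merged.setPackageRequired("layout", False)
    mmodel = merged.getModel()
    mplug = mmodel.getPlugin("layout")

    existing = {mplug.getLayout(i).getId() for i in range(mplug.getNumLayouts())}
    for i in range(src_plug.getNumLayouts()):
        lay = src_plug.getLayout(i)
        if lay.getId() in existing:
            raise ValueError(
                f"both documents carry a layout with id {lay.getId()!r}; "
                "rename one before merging"
            )
        mplug.addLayout(lay)

    species_ids = {mmodel.getSpecies(i).getId() for i in range(mmodel.getNumSpecies())}
    reaction_ids = {mmodel.getReaction(i).getId() for i in range(mmodel.getNumReactions())}

    report = GlyphMatchReport()
    for li in range(mplug.getNumLayouts()):
        lay = mplug.getLayout(li)
        for i in range(lay.getNumSpeciesGlyphs()):
            sg = lay.getSpeciesGlyph(i)
            attrs = _get_annotation(sg, "node") or {}
            candidates = [attrs.get("biggId"), sg.getSpeciesId() or None, sg.getName() or None]
            hit = next((c for c in candidates if c in species_ids), None)
            if hit is not None:
                sg.setSpeciesId(hit)
                report.matched_species.append(sg.getId())
            else:
                report.unmatched_species.append(sg.getId())
        for i in range(lay.getNumReactionGlyphs()):
            rg = lay.getReactionGlyph(i)
            attrs = _get_annotation(rg, "reaction") or {}
            candidates = [attrs.get("biggId"), rg.getReactionId() or None, rg.getName() or None]
            hit = next((c for c in candidates if c in reaction_ids), None)
            if hit is not None:
                rg.setReactionId(hit)
                report.matched_reactions.append(rg.getId())
            else:
                report.unmatched_reactions.append(rg.getId())
    return merged, report


def write_sbml(doc: libsbml.SBMLDocument, target: Union[str, Path]) -> None:
    """Write an SBML document; a ``.gz`` suffix gzip-compresses (mtime pinned)."""
    payload = libsbml.writeSBMLToString(doc).encode("utf-8")
    if str(target).endswith(".gz"):
        import io

        buf = io.BytesIO()
        with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as gz:
            gz.write(payload)
        payload = buf.getvalue()
    Path(target).write_bytes(payload)
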