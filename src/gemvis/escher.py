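"""Read and write Escher pathway-map JSON documents.

An Escher map is a two-element JSON array ``[header, body]``.  The header
carries the map name and a schema URL (the ``1-0-x`` family is supported);
the body holds ``nodes``, ``reactions``, ``canvas`` and ``text_labels``.
Files may be gzip-compressed (``.json.gz``); compression is detected from
the two magic bytes, never from the file name.

Writing is deterministic: the same map always serialises to the same bytes
(sorted keys, fixed separators), so a write–read–write cycle is bit-stable.
"""
from __future__ import annotations

import gzip
import io
import json
import logging
import re
from pathlib import Path
from typing import BinaryIO, Union

from .maps import (
    Canvas,
    MapIntegrityError,
    MapNode,
    MetabolicMap,
    ReactionEdge,
    Segment,
    TextLabel,
)

__all__ = [
    "read_escher_json",
    "write_escher_json",
    "EscherParseError",
    "EscherSchemaError",
]

log = logging.getLogger(__name__)

GZIP_MAGIC = b"\x1f\x8b"

#: Keys this reader interprets; anything else on a node/reaction is carried
#: opaquely through round trips in ``extras``.
_NODE_KEYS = {"node_type", "x", "y", "bigg_id", "name", "node_is_primary", "label_x", "label_y"}
_REACTION_KEYS = {"bigg_id", "name", "label_x", "label_y", "reversibility", "segments"}

_SCHEMA_RE = re.compile(r"(\d+-\d+-\d+)")


class EscherParseError(ValueError):
    """The document is not syntactically valid JSON."""


class EscherSchemaError(ValueError):
    """The document is JSON but not a supported Escher map."""


def _read_bytes(source: Union[str, Path, BinaryIO]) -> bytes:
    if isinstance(source, (str, Path)):
        return Path(source).read_bytes()
    return source.read()


def read_escher_json(
    source: Union[str, Path, BinaryIO], allow_gzip: bool = True
) -> MetabolicMap:
    """Parse an Escher map document into a validated :class:`MetabolicMap`.

    Parameters
    ----------
    source
        File path or binary stream holding the ``[header, body]`` document,
        optionally gzip-compressed.
    allow_gzip
        When true (default), gzip input is detected by its magic bytes and
        decompressed transparently.

    Raises
    ------
    EscherParseError
        Malformed JSON; the message names the byte offset.
    EscherSchemaError
        Missing required section or unsupported schema version.
    MapIntegrityError
        Dangling segment references.
    """
    raw = _read_bytes(source)
    if allow_gzip and raw[:2] == GZIP_MAGIC:
        raw = gzip.decompress(raw)
    try:
        doc = json.loads(raw.decode("utf-8"))
    except json.JSONDecodeError as exc:
        raise EscherParseError(
            f"malformed JSON at byte offset {exc.pos}: {exc.msg}"
        ) from exc

    if not (isinstance(doc, list) and len(doc) == 2):
        raise EscherSchemaError(
            "an Escher map is a two-element JSON array [header, body]; "
            f"got {type(doc).__name__}"
        )
    header, body = doc
    if not isinstance(header, dict) or not isinstance(body, dict):
        raise EscherSchemaError("header and body must be JSON objects")

    schema_version = _sniff_schema(header)

    for section in ("nodes", "reactions", "canvas"):
        if section not in body:
            raise EscherSchemaError(f"missing required section {section!r}")

    cv = body["canvas"]
    canvas = Canvas(
        x=float(cv.get("x", 0.0)),
        y=float(cv.get("y", 0.0)),
        width=float(cv["width"]),
        height=float(cv["height"]),
    )

    m = MetabolicMap(
        map_name=str(header.get("map_name", "")),
        schema_version=schema_version,
        canvas=canvas,
    )

    for nid, nd in body["nodes"].items():
        kind = nd.get("node_type")
        if kind not in ("metabolite", "midmarker", "multimarker"):
            raise EscherSchemaError(f"node {nid!r}: unknown node_type {kind!r}")
        extras = {k: v for k, v in nd.items() if k not in _NODE_KEYS}
        m.add_node(
            MapNode(
                node_id=str(nid),
                kind=kind,
                x=float(nd["x"]),
                y=float(nd["y"]),
                bigg_id=str(nd.get("bigg_id", "") or ""),
                display_name=str(nd.get("name", "") or ""),
                is_primary=bool(nd.get("node_is_primary", False)),
                label_x=_opt_float(nd.get("label_x")),
                label_y=_opt_float(nd.get("label_y")),
                extras=extras,
            )
        )

    for rid, rd in body["reactions"].items():
        segments = []
        for sid in sorted(rd.get("segments", {}), key=_seg_sort_key):
            sd = rd["segments"][sid]
            segments.append(
                Segment(
                    from_node_id=str(sd["from_node_id"]),
                    to_node_id=str(sd["to_node_id"]),
                    b1=_opt_point(sd.get("b1")),
                    b2=_opt_point(sd.get("b2")),
                )
            )
        extras = {k: v for k, v in rd.items() if k not in _REACTION_KEYS}
        m.add_reaction(
            ReactionEdge(
                reaction_id=str(rid),
                bigg_id=str(rd.get("bigg_id", "") or ""),
                label_x=float(rd.get("label_x", 0.0)),
                label_y=float(rd.get("label_y", 0.0)),
                reversibility=bool(rd.get("reversibility", False)),
                segments=segments,
                extras=extras,
            )
        )

    for tl in body.get("text_labels", {}).values():
        m.text_labels.append(
            TextLabel(text=str(tl.get("text", "")), x=float(tl["x"]), y=float(tl["y"]))
        )

    m.validate()
    return m


def _sniff_schema(header: dict) -> str:
    """Extract the n-n-n schema version; reject unsupported majors."""
    schema = str(header.get("schema", ""))
    match = _SCHEMA_RE.search(schema)
    if not match:
        log.warning("no schema version in header; assuming 1-0-4")
        return "1-0-4"
    version = match.group(1)
    major = version.split("-")[0]
    if major != "1":
        raise EscherSchemaError(f"unsupported Escher schema major version: {version}")
    return version


def _seg_sort_key(sid: str):
    # Escher segment ids are numeric strings; sort numerically so the drawn
    # order is stable, falling back to lexicographic for foreign ids.
    try:
        return (0, int(sid), "")
    except ValueError:
        return (1, 0, sid)


def _opt_float(v):
    return None if v is None else float(v)


def _opt_point(v):
    if v is None:
        return None
    return (float(v["x"]), float(v["y"]))


def write_escher_json(
    metabolic_map: MetabolicMap, target: Union[str, Path, BinaryIO, None] = None
) -> bytes:
    """Serialise a map to Escher JSON; returns the bytes and optionally writes.

    A target path ending in ``.gz`` is gzip-compressed (with mtime pinned to
    zero so output bytes stay deterministic).
    """
    metabolic_map.validate()
    header = {
        "map_name": metabolic_map.map_name,
        "map_id": "",
        "map_description": "",
        "homepage": "https://escher.github.io",
        "schema": f"https://escher.github.io/escher/jsonschema/{metabolic_map.schema_version}#",
    }
    nodes = {}
    for nid, n in metabolic_map.nodes.items():
        nd: dict = {"node_type": n.kind, "x": n.x, "y": n.y}
        if n.kind == "metabolite":
            nd["bigg_id"] = n.bigg_id
            nd["name"] = n.display_name
            nd["node_is_primary"] = n.is_primary
            if n.label_x is not None:
                nd["label_x"] = n.label_x
                nd["label_y"] = n.label_y
        nd.update(n.extras)
        nodes[nid] = nd
    reactions = {}
    for rid, r in metabolic_map.reactions.items():
        segs = {}
        for k, s in enumerate(r.segments):
            sd: dict = {"from_node_id": s.from_node_id, "to_node_id": s.to_node_id}
            sd["b1"] = {"x": s.b1[0], "y": s.b1[1]} if s.b1 else None
            sd["b2"] = {"x": s.b2[0], "y": s.b2[1]} if s.b2 else None
            segs[str(k)] = sd
        rd: dict = {
            "bigg_id": r.bigg_id,
            "name": r.extras.get("name", r.bigg_id),
            "label_x": r.label_x,
            "label_y": r.label_y,
            "reversibility": r.reversibility,
            "segments": segs,
        }
        rd.update({k: v for k, v in r.extras.items() if k != "name"})
        reactions[rid] = rd
    body = {
        "reactions": reactions,
        "nodes": nodes,
        "text_labels": {
            str(i): {"text": t.text, "x": t.x, "y": t.y}
            for i, t in enumerate(metabolic_map.text_labels)
        },
        "canvas": {
            "x": metabolic_map.canvas.x,
            "y": metabolic_map.canvas.y,
            "width": metabolic_map.canvas.width,
            "height": metabolic_map.canvas.height,
        },
    }
    payload = json.dumps([header, body], sort_keys=True, separators=(",", ":")).encode()

    if target is not None:
        if isinstance(target, (str, Path)):
            out = payload
            if str(target).endswith(".gz"):
                buf = io.BytesIO()
                with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as gz:
                    gz.write(payload)
                out = buf.getvalue()
            Path(target).write_bytes(out)
        else:
            target.write(payload)
    return payload
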