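"""Synthetic maps, models and time courses with known ground truth.

The generator emulates the three inputs of the animation pipeline on a
small scale: a connected chain/branch pathway map (metabolite glyphs on a
grid, one midmarker per reaction, gentle Bezier curves), a matching SBML
L3V1 model whose species ids equal the map's BiGG ids, and per-metabolite
time series drawn from simple named dynamics (constant, linear,
exponential decay, logistic rise, sinusoid — the qualitative shapes of
metabolite pools during cold storage of blood cells) plus seeded Gaussian
noise.  The noise-free generating functions are returned alongside the CSV
so tests can compare interpolants against ground truth.

All randomness flows through an explicit seed; no global random state.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import libsbml
import numpy as np

from .maps import Canvas, MapNode, MetabolicMap, ReactionEdge, Segment

__all__ = ["FixtureSpec", "make_toy_map", "make_toy_timecourse", "make_camera_text",
           "write_fixture_files"]

DYNAMICS = ("constant", "linear", "exp_decay", "logistic", "sinusoid")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic data set."""

    n_metabolites: int = 6
    n_reactions: Optional[int] = None  # default: chain, n_metabolites - 1
    grid_spacing: float = 80.0
    n_times: int = 8
    time_span: float = 10.0  # e.g. days of storage
    dynamics: str = "exp_decay"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_metabolites < 1:
            raise ValueError("need at least one metabolite")
        if self.n_reactions is None:
            self.n_reactions = max(self.n_metabolites - 1, 1)
        if self.n_reactions < 1:
            raise ValueError("need at least one reaction")
        if self.n_times < 1:
            raise ValueError("need at least one time point")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dynamics not in DYNAMICS:
            raise ValueError(f"dynamics must be one of {DYNAMICS}")


def make_toy_map(spec: FixtureSpec) -> tuple[MetabolicMap, libsbml.SBMLDocument]:
    """Build a connected chain map plus the matching SBML L3V1 model.

    Metabolites sit on a serpentine grid; reaction j connects metabolite j
    to j+1 through a midmarker, with mild Bezier control points so curve
    handling is exercised.  Model species ids equal the map's BiGG ids
    (``met{j}_c``), all in one cytosol compartment.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_metabolites
    g = spec.grid_spacing
    per_row = max(int(math.ceil(math.sqrt(n))), 2)

    m = MetabolicMap(map_name=f"toy_map_{spec.seed}", schema_version="1-0-4")
    positions = []
    for j in range(n):
        row, col = divmod(j, per_row)
        if row % 2 == 1:  # serpentine: keep consecutive metabolites adjacent
            col = per_row - 1 - col
        x = 100.0 + col * g + float(rng.uniform(-g / 8, g / 8))
        y = 100.0 + row * g + float(rng.uniform(-g / 8, g / 8))
        positions.append((x, y))
        m.add_node(
            MapNode(
                node_id=str(j),
                kind="metabolite",
                x=x,
                y=y,
                bigg_id=f"met{j}_c",
                display_name=f"Metabolite {j}",
                is_primary=True,
                label_x=x + 15.0,
                label_y=y - 8.0,
            )
        )

    n_rxn = min(spec.n_reactions, max(n - 1, 1))
    for j in range(n_rxn):
        a = j % n
        b = (j + 1) % n
        ax, ay = positions[a]
        bx, by = positions[b]
        mx, my = (ax + bx) / 2.0, (ay + by) / 2.0
        mid_id = f"m{j}"
        m.add_node(MapNode(node_id=mid_id, kind="midmarker", x=mx, y=my))
        bend = float(rng.uniform(-g / 6, g / 6))
        m.add_reaction(
            ReactionEdge(
                reaction_id=f"r{j}",
                bigg_id=f"RXN{j}",
                label_x=mx,
                label_y=my - 20.0,
                reversibility=bool(j % 2),
                segments=[
                    Segment(
                        str(a), mid_id,
                        b1=(ax + (mx - ax) / 3.0, ay + bend),
                        b2=(ax + 2 * (mx - ax) / 3.0, ay + bend),
                    ),
                    Segment(mid_id, str(b)),
                ],
            )
        )

    xs = [nd.x for nd in m.nodes.values()]
    ys = [nd.y for nd in m.nodes.values()]
    m.canvas = Canvas(
        x=min(xs) - 60.0,
        y=min(ys) - 60.0,
        width=(max(xs) - min(xs)) + 120.0,
        height=(max(ys) - min(ys)) + 120.0,
    )
    m.text_labels.append(_title_label(m))
    m.validate()
    return m, _build_model(m, n_rxn)


def _title_label(m: MetabolicMap):
    from .maps import TextLabel

    return TextLabel(text=m.map_name, x=m.canvas.x + 10.0, y=m.canvas.y + 14.0)


def _build_model(m: MetabolicMap, n_rxn: int) -> libsbml.SBMLDocument:
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(m.map_name.replace("-", "_"))
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    comp.setSize(1.0)
    for node in m.metabolite_nodes():
        sp = model.createSpecies()
        sp.setId(node.bigg_id)
        sp.setName(node.display_name)
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
    mets = sorted(m.metabolite_nodes(), key=lambda n: int(n.node_id))
    for j in range(n_rxn):
        rxn = model.createReaction()
        rxn.setId(f"RXN{j}")
        rxn.setReversible(bool(j % 2))
        rxn.setFast(False)
        sub = rxn.createReactant()
        sub.setSpecies(mets[j % len(mets)].bigg_id)
        sub.setStoichiometry(1.0)
        sub.setConstant(True)
        prod = rxn.createProduct()
        prod.setSpecies(mets[(j + 1) % len(mets)].bigg_id)
        prod.setStoichiometry(1.0)
        prod.setConstant(True)
    return doc


# ---------------------------------------------------------------------------
# time courses


def _dynamics_fn(kind: str, rng: np.random.Generator, span: float) -> Callable:
    v0 = float(rng.uniform(1.0, 10.0))
    if kind == "constant":
        return lambda t: np.full_like(np.asarray(t, dtype=float), v0)
    if kind == "linear":
        slope = float(rng.uniform(-v0 / span, 2.0 * v0 / span))
        return lambda t: v0 + slope * np.asarray(t, dtype=float)
    if kind == "exp_decay":
        lam = float(rng.uniform(0.1, 0.5)) * 8.0 / span
        return lambda t: v0 * np.exp(-lam * np.asarray(t, dtype=float))
    if kind == "logistic":
        k = float(rng.uniform(0.8, 2.0)) * 8.0 / span
        t0 = span / 2.0
        return lambda t: v0 / (1.0 + np.exp(-k * (np.asarray(t, dtype=float) - t0)))
    if kind == "sinusoid":
        w = 2.0 * math.pi / span
        return lambda t: v0 * (1.2 + np.sin(w * np.asarray(t, dtype=float)))
    raise ValueError(kind)


def make_toy_timecourse(
    metabolic_map: MetabolicMap, spec: FixtureSpec
) -> tuple[bytes, dict[str, Callable]]:
    """CSV bytes (one row per metabolite, numeric time headers) + the
    noise-free generating function per metabolite id."""
    if not metabolic_map.metabolite_nodes():
        raise ValueError("map has no metabolite nodes")
    rng = np.random.default_rng(spec.seed + 1)
    times = np.linspace(0.0, spec.time_span, spec.n_times)
    truth: dict[str, Callable] = {}
    lines = ["metabolite," + ",".join(f"{t:.12g}" for t in times)]
    for node in metabolic_map.metabolite_nodes():
        fn = _dynamics_fn(spec.dynamics, rng, spec.time_span)
        truth[node.bigg_id] = fn
        vals = np.asarray(fn(times), dtype=float)
        if spec.noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.shape)
        lines.append(node.bigg_id + "," + ",".join(f"{v:.10g}" for v in vals))
    return ("\n".join(lines) + "\n").encode("utf-8"), truth


def make_camera_text(metabolic_map: MetabolicMap, zoom: float = 1.0) -> str:
    """A simple pan across the map: top-left to center to bottom-right."""
    c = metabolic_map.canvas
    pts = [
        (c.x, c.y),
        (c.x + c.width / 4.0, c.y + c.height / 4.0),
        (c.x + c.width / 2.0, c.y + c.height / 2.0),
    ]
    coords = "\t".join(f"{v:g}" for p in pts for v in p)
    return f"{zoom:g}\t{coords}\n"


def write_fixture_files(out_dir, spec: FixtureSpec) -> dict[str, Path]:
    """Emit map.json, model.xml.gz, data.csv and camera.csv to a directory,
    in the exact external dialects the pipeline reads."""
    from .escher import write_escher_json
    from .sbml_layout import write_sbml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m, model_doc = make_toy_map(spec)
    csv_bytes, _ = make_toy_timecourse(m, spec)
    paths = {
        "map": out / "map.json",
        "model": out / "model.xml.gz",
        "data": out / "data.csv",
        "camera": out / "camera.csv",
    }
    write_escher_json(m, paths["map"])
    write_sbml(model_doc, paths["model"])
    paths["data"].write_bytes(csv_bytes)
    paths["camera"].write_text(make_camera_text(m))
    return paths
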