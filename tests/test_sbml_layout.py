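"""Escher <-> SBML Layout conversion and layout-into-model merging."""
import gzip

import libsbml
import pytest

from gemvis.fixtures import FixtureSpec, make_toy_map
from gemvis.maps import Canvas, MapNode, MetabolicMap, ReactionEdge, Segment
from gemvis.sbml_layout import (
    GlyphMatchReport,
    NoLayoutError,
    escher_to_sbml_layout,
    merge_layout_into_model,
    read_sbml,
    read_sbml_layout,
    sanitize_sid,
    validate_sbml,
    write_sbml,
)

from conftest import random_map


def to_bytes(doc) -> bytes:
    return libsbml.writeSBMLToString(doc).encode()


class TestEscherToSbml:
    @pytest.mark.parametrize("seed", [0, 5, 42])
    def test_round_trip_preserves_ids_kinds_centers(self, seed):
        m = random_map(seed)
        again, _doc = read_sbml_layout(to_bytes(escher_to_sbml_layout(m)))
        assert m.diff(again, tol=1e-6) == []

    def test_bounding_box_centered_on_node(self, toy_map):
        doc = escher_to_sbml_layout(toy_map, species_extent=20.0)
        layout = doc.getModel().getPlugin("layout").getLayout(0)
        sg = layout.getSpeciesGlyph(0)
        bb = sg.getBoundingBox()
        node = next(n for n in toy_map.metabolite_nodes())
        assert bb.getPosition().getXOffset() == pytest.approx(node.x - 10.0)
        assert bb.getPosition().getYOffset() == pytest.approx(node.y - 10.0)

    def test_glyph_counts_match_map(self, toy_map):
        doc = escher_to_sbml_layout(toy_map)
        layout = doc.getModel().getPlugin("layout").getLayout(0)
        assert layout.getNumSpeciesGlyphs() == len(toy_map.metabolite_nodes())
        assert layout.getNumReactionGlyphs() == len(toy_map.reactions)

    def test_markers_get_no_species_glyph(self, toy_map):
        doc = escher_to_sbml_layout(toy_map)
        layout = doc.getModel().getPlugin("layout").getLayout(0)
        ids = {layout.getSpeciesGlyph(i).getId() for i in range(layout.getNumSpeciesGlyphs())}
        assert len(ids) == len(toy_map.metabolite_nodes())  # none for markers

    def test_validates_with_zero_errors(self, toy_map, toy_model):
        assert validate_sbml(escher_to_sbml_layout(toy_map)) == []
        assert validate_sbml(escher_to_sbml_layout(toy_map, toy_model)) == []

    def test_numeric_node_id_sanitized_and_invertible(self):
        m = MetabolicMap(canvas=Canvas(width=100, height=100))
        m.add_node(MapNode("42", "metabolite", 10.0, 10.0, bigg_id="atp_c"))
        m.add_node(MapNode("mid", "midmarker", 20.0, 10.0))
        m.add_node(MapNode("43", "metabolite", 30.0, 10.0, bigg_id="adp_c"))
        m.add_reaction(ReactionEdge("9", "ATPASE", segments=[
            Segment("42", "mid"), Segment("mid", "43")]))
        doc = escher_to_sbml_layout(m)
        layout = doc.getModel().getPlugin("layout").getLayout(0)
        sid = layout.getSpeciesGlyph(0).getId()
        assert sid == "ng_42"  # valid SId, deterministic
        again, _ = read_sbml_layout(to_bytes(doc))
        assert set(again.nodes) == {"42", "mid", "43"}

    def test_conversion_deterministic_bytes(self, toy_map):
        b1 = to_bytes(escher_to_sbml_layout(toy_map))
        b2 = to_bytes(escher_to_sbml_layout(toy_map))
        assert b1 == b2


class TestSanitizeSid:
    def test_collisions_get_disambiguator(self):
        taken: set = set()
        a = sanitize_sid("a b", "ng_", taken)
        b = sanitize_sid("a.b", "ng_", taken)
        assert a == "ng_a_b" and b == "ng_a_b_2"

    def test_result_is_valid_sid(self):
        import re

        sid = sanitize_sid("12:3/x", "rg_", set())
        assert re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", sid)


class TestReadSbmlLayout:
    def test_species_glyph_center_is_bbox_center(self):
        # hand-built foreign document: bbox (90, 190, 20, 20) -> center (100, 200)
        ns = libsbml.SBMLNamespaces(3, 1, "layout", 1)
        doc = libsbml.SBMLDocument(ns)
        doc.setPackageRequired("layout", False)
        model = doc.createModel()
        model.setId("m")
        lns = libsbml.LayoutPkgNamespaces(3, 1, 1)
        layout = model.getPlugin("layout").createLayout()
        layout.setId("l1")
        layout.setDimensions(libsbml.Dimensions(lns, 400, 300))
        sg = layout.createSpeciesGlyph()
        sg.setId("sg1")
        sg.setBoundingBox(libsbml.BoundingBox(lns, "bb", 90.0, 190.0, 20.0, 20.0))
        m, _ = read_sbml_layout(to_bytes(doc))
        node = m.nodes["sg1"]
        assert (node.x, node.y) == (100.0, 200.0)

    def test_no_layout_error_distinct_from_parse_error(self):
        doc = libsbml.SBMLDocument(3, 1)
        doc.createModel().setId("m")
        with pytest.raises(NoLayoutError):
            read_sbml_layout(to_bytes(doc))

    def test_gzip_compressed_document(self, toy_map, tmp_path):
        doc = escher_to_sbml_layout(toy_map)
        path = tmp_path / "layout.xml.gz"
        write_sbml(doc, path)
        assert path.read_bytes()[:2] == b"\x1f\x8b"
        again, _ = read_sbml_layout(path)
        assert toy_map.diff(again, tol=1e-6) == []


class TestMerge:
    def layout_for(self, n_species: int):
        """A map referencing the first n_species of the 3-species toy model."""
        m, model = make_toy_map(FixtureSpec(n_metabolites=3, seed=11))
        if n_species < 3:
            # rename one bigg id so it cannot match the model
            victim = m.nodes["2"]
            victim.bigg_id = "unknown_x"
        return m, model

    def test_unmatched_glyphs_reported(self):
        m, model = self.layout_for(2)
        merged, report = merge_layout_into_model(model, escher_to_sbml_layout(m))
        assert len(report.unmatched_species) == 1
        assert len(report.matched_species) == 2
        # model's species list intact
        assert merged.getModel().getNumSpecies() == 3

    def test_merge_then_read_returns_layout_unchanged(self, toy_map, toy_model):
        merged, _ = merge_layout_into_model(toy_model, escher_to_sbml_layout(toy_map))
        again, _ = read_sbml_layout(to_bytes(merged))
        assert toy_map.diff(again, tol=1e-6) == []

    def test_merged_document_validates(self, toy_map, toy_model):
        merged, _ = merge_layout_into_model(toy_model, escher_to_sbml_layout(toy_map))
        assert validate_sbml(merged) == []

    def test_level_version_mismatch_rejected(self, toy_map):
        old = libsbml.SBMLDocument(2, 4)
        old.createModel().setId("m")
        with pytest.raises(ValueError, match="Level 3 Version 1"):
            merge_layout_into_model(old, escher_to_sbml_layout(toy_map))

    def test_duplicate_layout_id_rejected(self, toy_map, toy_model):
        ldoc = escher_to_sbml_layout(toy_map)
        merged, _ = merge_layout_into_model(toy_model, ldoc)
        with pytest.raises(ValueError, match="layout_1"):
            merge_layout_into_model(merged, ldoc)

    def test_merged_gzip_round_trip(self, toy_map, toy_model, tmp_path):
        merged, _ = merge_layout_into_model(toy_model, escher_to_sbml_layout(toy_map))
        path = tmp_path / "merged.xml.gz"
        write_sbml(merged, path)
        doc = read_sbml(path)
        assert doc.getModel().getNumSpecies() == toy_model.getModel().getNumSpecies()
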