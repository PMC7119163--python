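"""Convert a pathway map between Escher JSON and SBML Layout.

Builds a small synthetic map, writes it as Escher JSON, converts it to an
SBML Level 3 document with the Layout extension, reads it back, and shows
that ids and coordinates survive the round trip.
"""
from pathlib import Path
import tempfile

import libsbml

from gemvis import FixtureSpec, make_toy_map, read_escher_json, write_escher_json
from gemvis.sbml_layout import escher_to_sbml_layout, read_sbml_layout, validate_sbml

workdir = Path(tempfile.mkdtemp())

metabolic_map, model_doc = make_toy_map(FixtureSpec(n_metabolites=6, seed=42))
escher_path = workdir / "map.json"
write_escher_json(metabolic_map, escher_path)
print(f"wrote {escher_path.name}: {len(metabolic_map.nodes)} nodes, "
      f"{len(metabolic_map.reactions)} reactions")

layout_doc = escher_to_sbml_layout(metabolic_map, model_doc)
errors = validate_sbml(layout_doc)
print(f"SBML validation errors: {len(errors)}")  # 0 = standards-conformant

recovered, _doc = read_sbml_layout(libsbml.writeSBMLToString(layout_doc).encode())
differences = metabolic_map.diff(recovered, tol=1e-6)
print(f"round-trip differences at 1e-6 map units: {len(differences)}")
# 0 differences: every node id, kind and glyph center is preserved, so a
# map drawn once can move freely between the two ecosystems.
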