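import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from gemvis.fixtures import FixtureSpec, make_toy_map, make_toy_timecourse
from gemvis.timecourse import read_timecourse_csv


@pytest.fixture(scope="session")
def toy():
    """A 6-metabolite chain map with its matching SBML model."""
    return make_toy_map(FixtureSpec(n_metabolites=6, seed=3))


@pytest.fixture(scope="session")
def toy_map(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_table(toy_map):
    csv_bytes, _truth = make_toy_timecourse(
        toy_map, FixtureSpec(n_metabolites=6, seed=3, dynamics="exp_decay")
    )
    return read_timecourse_csv(csv_bytes)


def minimal_escher_doc() -> list:
    """The smallest well-formed Escher document used across parser tests."""
    return [
        {"map_name": "mini", "schema": "https://escher.github.io/escher/jsonschema/1-0-4#"},
        {
            "nodes": {
                "1": {
                    "node_type": "metabolite",
                    "x": 100.0,
                    "y": 200.0,
                    "bigg_id": "glc__D_c",
                    "name": "D-Glucose",
                    "node_is_primary": True,
                    "label_x": 110.0,
                    "label_y": 195.0,
                },
                "2": {"node_type": "midmarker", "x": 150.0, "y": 200.0},
                "3": {
                    "node_type": "metabolite",
                    "x": 200.0,
                    "y": 200.0,
                    "bigg_id": "g6p_c",
                    "name": "Glucose 6-phosphate",
                    "node_is_primary": True,
                },
            },
            "reactions": {
                "10": {
                    "bigg_id": "HEX1",
                    "label_x": 150.0,
                    "label_y": 180.0,
                    "reversibility": False,
                    "segments": {
                        "0": {
                            "from_node_id": "1",
                            "to_node_id": "2",
                            "b1": {"x": 120.0, "y": 190.0},
                            "b2": {"x": 140.0, "y": 190.0},
                        },
                        "1": {"from_node_id": "2", "to_node_id": "3", "b1": None, "b2": None},
                    },
                }
            },
            "text_labels": {"0": {"text": "Glycolysis", "x": 90.0, "y": 90.0}},
            "canvas": {"x": 0.0, "y": 0.0, "width": 400.0, "height": 300.0},
        },
    ]


@pytest.fixture()
def mini_doc():
    return minimal_escher_doc()


def random_map(seed: int, n_metabolites: int = 5):
    """A seeded random fixture map (chain topology, jittered grid)."""
    return make_toy_map(FixtureSpec(n_metabolites=n_metabolites, seed=seed))[0]
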