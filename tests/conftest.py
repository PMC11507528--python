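"""Shared fixtures: small planted studies, networks, and pipeline inputs.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk except what a fixture itself writes to tmp_path.
"""

from __future__ import annotations

import pytest

import omixprox as ox
from omixprox.synthetic_data import gen_pipeline_inputs

TOY_GEOMETRY = {
    "CANDA": {"transcriptome": 0, "genome": 1, "protein": 1},  # selected
    "CANDB": {"transcriptome": 1, "genome": 1, "protein": 1},  # no zero level
    "CANDC": {"transcriptome": 0, "genome": 1, "protein": 2},  # component > 1
}


@pytest.fixture(scope="session")
def planted_network():
    """60-node network with three candidates at known hop distances."""
    return ox.gen_network(
        n_nodes=60,
        mean_degree=3.0,
        seed=7,
        sig_sizes={"transcriptome": 4, "genome": 4, "protein": 4},
        planted_geometry=TOY_GEOMETRY,
    )


@pytest.fixture(scope="session")
def planted_interactome(planted_network):
    """The score-filtered InteractionNetwork of the planted fixture."""
    return ox.filter_by_score(planted_network.edges, min_score=700)


@pytest.fixture(scope="session")
def small_study():
    """Low-noise two-group study with 12 up / 6 down planted genes."""
    return ox.gen_expression(
        n_genes=300, n_per_group=10, n_up=12, n_down=6,
        lfc=3.0, sigma=0.25, seed=11,
    )


@pytest.fixture()
def pipeline_inputs(tmp_path):
    return gen_pipeline_inputs(tmp_path, seed=11)
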