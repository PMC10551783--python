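from __future__ import annotations

import pytest

from relgraph.pipeline import bundle_to_graph
from relgraph.synthetic import (
    SimulationConfig,
    generate_prediction_records,
    make_planted_patterns,
    plant_drug_paths,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A modest background corpus shared by read-only tests."""
    cfg = SimulationConfig(n_papers=60, n_entities=100, seed=11)
    return generate_prediction_records(cfg)


@pytest.fixture(scope="session")
def planted_bundle():
    """Background corpus with 5 pattern-a, 3 pattern-b and 2 pattern-c paths."""
    cfg = SimulationConfig(n_papers=40, n_entities=80, seed=5)
    bundle = generate_prediction_records(cfg)
    patterns = (
        make_planted_patterns("a", 5, id_offset=0)
        + make_planted_patterns("b", 3, id_offset=20)
        + make_planted_patterns("c", 2, id_offset=40)
    )
    return plant_drug_paths(bundle, patterns, seed=17)


@pytest.fixture(scope="session")
def planted_graph(planted_bundle):
    return bundle_to_graph(planted_bundle)
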