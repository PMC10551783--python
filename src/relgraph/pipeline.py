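"""End-to-end convenience: prediction records → knowledge graph → discovery.

Thin orchestration over the module-level operations, mirroring how the
analysis is run in practice: drop null records, collapse inverse
directions, merge triples, build the typed property graph, then query it
for existing drugs and novel drug paths.
"""

from __future__ import annotations

from typing import Sequence

from .aggregate import AggregatedTriple, aggregate_predictions
from .discovery import (
    DrugPath,
    PATTERNS,
    count_unique_path_drugs,
    enumerate_drug_paths,
    find_existing_drugs,
    rank_paths,
)
from .graph import KnowledgeGraph, NodeRecord, build_graph
from .synthetic import DEFAULT_TARGET_ID, SyntheticBundle

__all__ = ["bundle_to_triples", "bundle_to_graph", "discover_drug_paths"]


def bundle_to_triples(bundle: SyntheticBundle) -> list[AggregatedTriple]:
    """Null removal + direction canonicalization + triple merge for a bundle."""
    return aggregate_predictions(bundle.predictions, bundle.inverse_map)


def bundle_to_graph(bundle: SyntheticBundle) -> KnowledgeGraph:
    """Aggregate a bundle's predictions and assemble the knowledge graph."""
    triples = bundle_to_triples(bundle)
    entity_table = {
        eid: NodeRecord(eid, name, etype) for eid, (name, etype) in bundle.entities.items()
    }
    return build_graph(triples, entity_table)


def discover_drug_paths(
    graph: KnowledgeGraph,
    target_id: str = DEFAULT_TARGET_ID,
    patterns: Sequence[str] = ("a", "b", "c"),
    class_map=None,
    min_sources: int = 1,
) -> tuple[list[DrugPath], dict[str, int]]:
    """Enumerate and rank all requested path patterns against one target.

    Returns the ranked path list and the per-pattern unique-drug counts.
    """
    all_paths: list[DrugPath] = []
    for pattern in patterns:
        if pattern not in PATTERNS:
            raise KeyError(pattern)
        all_paths.extend(
            enumerate_drug_paths(graph, target_id, pattern, class_map, min_sources=min_sources)
        )
    ranked = rank_paths(all_paths, graph, target_id)
    return ranked, count_unique_path_drugs(ranked)


# re-exported for convenience in notebooks/examples
existing_drugs = find_existing_drugs
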