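"""Existing-drug identification and novel 4-node drug-path discovery.

Relation labels are grouped into coarse edge classes:

* ``TREATS`` — drug → disease therapeutic relations (directional),
* ``AFFECTS`` — drug → gene effect relations (directional),
* ``ASSOCIATED`` — entity–entity association (symmetric),
* ``DRUG_DRUG_ASSOC`` — chemical–chemical association (symmetric),
* ``OTHER`` — everything else.

An *existing* drug is one satisfying three conditions against a target
disease: (1) it affects a gene that is associated with the target, (2) it
treats a disease that is associated with the target, and (3) every edge
used as evidence is supported by at least ``min_sources`` distinct papers
(default 2).  Hits are ranked by Adamic–Adar closeness to the target.

*Novel* candidates are drugs not directly connected to the target that
reach it through one of three typed 4-node paths:

* pattern a: drug →TREATS disease₂ —ASSOC— gene —ASSOC— target
  (same genetic process, different condition),
* pattern b: drug₁ →TREATS disease₂ ←TREATS drug₂ →TREATS target,
  plus a drug₁–drug₂ association (similarly treated condition),
* pattern c: drug →AFFECTS gene₁ —ASSOC— gene₂ —ASSOC— target
  (two connected genes).

In every pattern the second node must itself be associated with the target
(qualification edge), and the first-node drug must have no edge of any
class to the target in either direction.  Path sets are ranked by the
Adamic–Adar score between drug and target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import InvalidPatternError, MissingNodeError
from .graph import KnowledgeGraph

__all__ = [
    "RelationClass",
    "RelationClassMap",
    "ExistingDrugHit",
    "DrugPath",
    "PATTERNS",
    "find_existing_drugs",
    "enumerate_drug_paths",
    "rank_paths",
    "count_unique_path_drugs",
    "write_paths_json",
]


class RelationClass(str, Enum):
    TREATS = "TREATS"
    AFFECTS = "AFFECTS"
    ASSOCIATED = "ASSOCIATED"
    DRUG_DRUG_ASSOC = "DRUG_DRUG_ASSOC"
    OTHER = "OTHER"


#: Classes whose stored edge direction is ignored during matching.
SYMMETRIC_CLASSES = frozenset({RelationClass.ASSOCIATED, RelationClass.DRUG_DRUG_ASSOC})


class RelationClassMap:
    """Mapping from relation labels to coarse edge classes."""

    def __init__(self, mapping: Mapping[str, "RelationClass | str"]):
        self._map = {label: RelationClass(cls) for label, cls in mapping.items()}

    def class_of(self, label: str) -> RelationClass:
        return self._map.get(label, RelationClass.OTHER)

    def labels_in(self, cls: RelationClass) -> set[str]:
        return {lab for lab, c in self._map.items() if c is cls}

    def as_dict(self) -> dict[str, str]:
        return {lab: cls.value for lab, cls in self._map.items()}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict()), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RelationClassMap":
        return cls(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class ExistingDrugHit:
    """A drug meeting all three existing-drug conditions, with its evidence."""

    drug_id: str
    gene_evidence: tuple[tuple, ...]  # ((drug→gene edge), (gene–target edge)) pairs
    disease_evidence: tuple[tuple, ...]
    adamic_adar: float


@dataclass(frozen=True)
class DrugPath:
    """One 4-node drug→…→target path instance with evidence edges."""

    pattern: str  # "a" | "b" | "c"
    nodes: tuple[str, str, str, str]  # (drug, mid1, mid2, target)
    edges: tuple[tuple, ...]  # evidence rows incl. qualification edges
    adamic_adar: float | None = None

    @property
    def drug_id(self) -> str:
        return self.nodes[0]

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "nodes": list(self.nodes),
            "edges": [list(e) for e in self.edges],
            "adamic_adar": self.adamic_adar,
        }


#: Node-type templates per pattern: (drug, mid1, mid2); the 4th node is the target.
PATTERNS: dict[str, tuple[str, str, str]] = {
    "a": ("chemical", "disease", "gene"),
    "b": ("chemical", "disease", "chemical"),
    "c": ("chemical", "gene", "gene"),
}


def _class_edges(
    graph: KnowledgeGraph,
    u: str,
    v: str,
    cls: RelationClass,
    class_map: RelationClassMap,
    min_sources: int = 1,
) -> list[tuple]:
    """Edges between u and v matching a class, direction-aware.

    Directional classes (TREATS, AFFECTS) only match u→v edges; symmetric
    classes match either stored direction.
    """
    g = graph.digraph
    out: list[tuple] = []
    candidates = []
    if g.has_edge(u, v):
        candidates.extend((u, v, d) for d in g[u][v].values())
    if cls in SYMMETRIC_CLASSES and g.has_edge(v, u):
        candidates.extend((v, u, d) for d in g[v][u].values())
    for start, end, data in candidates:
        if class_map.class_of(data["relation"]) is cls and data["n_sources"] >= min_sources:
            out.append(
                (start, end, data["relation"], data["n_sources"],
                 data["prob_mean"], data["prob_sum"])
            )
    return out


def _directly_connected(graph: KnowledgeGraph, u: str, v: str) -> bool:
    """True when any edge of any relation class links u and v in either direction."""
    g = graph.digraph
    return g.has_edge(u, v) or g.has_edge(v, u)


def find_existing_drugs(
    graph: KnowledgeGraph,
    target_id: str,
    class_map: RelationClassMap,
    min_sources: int = 2,
) -> list[ExistingDrugHit]:
    """Drugs satisfying the three existing-drug conditions, ranked by Adamic–Adar.

    Condition 1: an AFFECTS edge to a gene that holds an ASSOCIATED edge to
    the target.  Condition 2: a TREATS edge to a disease that holds an
    ASSOCIATED edge to the target.  Condition 3: every evidence edge has
    ``n_sources >= min_sources``.  Ties in the ranking break
    lexicographically by drug ID.  An empty graph yields an empty table.
    """
    if graph.n_nodes == 0:
        return []
    if not graph.has_node(target_id):
        raise MissingNodeError(target_id)
    hits: list[ExistingDrugHit] = []
    for drug in graph.nodes_by_type("chemical"):
        if drug == target_id:
            continue
        gene_ev = []
        for gene in graph.nodes_by_type("gene"):
            affect = _class_edges(graph, drug, gene, RelationClass.AFFECTS, class_map, min_sources)
            if not affect:
                continue
            assoc = _class_edges(graph, gene, target_id, RelationClass.ASSOCIATED, class_map, min_sources)
            gene_ev.extend((a, b) for a in affect for b in assoc)
        disease_ev = []
        for disease in graph.nodes_by_type("disease"):
            if disease == target_id:
                continue
            treat = _class_edges(graph, drug, disease, RelationClass.TREATS, class_map, min_sources)
            if not treat:
                continue
            assoc = _class_edges(graph, disease, target_id, RelationClass.ASSOCIATED, class_map, min_sources)
            disease_ev.extend((a, b) for a in treat for b in assoc)
        if gene_ev and disease_ev:
            hits.append(
                ExistingDrugHit(
                    drug_id=drug,
                    gene_evidence=tuple(gene_ev),
                    disease_evidence=tuple(disease_ev),
                    adamic_adar=graph.adamic_adar(drug, target_id),
                )
            )
    return sorted(hits, key=lambda h: (-h.adamic_adar, h.drug_id))


def _pattern_edges(
    graph: KnowledgeGraph,
    pattern: str,
    drug: str,
    mid1: str,
    mid2: str,
    target: str,
    class_map: RelationClassMap,
    min_sources: int,
    qual_min_sources: int,
) -> "list[tuple] | None":
    """All template + qualification edges for one candidate node sequence.

    Returns None when any required edge is missing.
    """
    if pattern == "a":
        required = [
            (drug, mid1, RelationClass.TREATS, min_sources),
            (mid1, mid2, RelationClass.ASSOCIATED, min_sources),
            (mid2, target, RelationClass.ASSOCIATED, min_sources),
            (mid1, target, RelationClass.ASSOCIATED, qual_min_sources),
        ]
    elif pattern == "b":
        required = [
            (drug, mid1, RelationClass.TREATS, min_sources),
            (mid2, mid1, RelationClass.TREATS, min_sources),
            (mid2, target, RelationClass.TREATS, min_sources),
            (mid1, target, RelationClass.ASSOCIATED, qual_min_sources),
            (drug, mid2, RelationClass.DRUG_DRUG_ASSOC, qual_min_sources),
        ]
    elif pattern == "c":
        required = [
            (drug, mid1, RelationClass.AFFECTS, min_sources),
            (mid1, mid2, RelationClass.ASSOCIATED, min_sources),
            (mid2, target, RelationClass.ASSOCIATED, min_sources),
            (mid1, target, RelationClass.ASSOCIATED, qual_min_sources),
        ]
    else:
        raise InvalidPatternError(f"unknown pattern {pattern!r}; expected one of a, b, c")
    evidence: list[tuple] = []
    for u, v, cls, ms in required:
        edges = _class_edges(graph, u, v, cls, class_map, ms)
        if not edges:
            return None
        evidence.extend(edges)
    return evidence


def enumerate_drug_paths(
    graph: KnowledgeGraph,
    target_id: str,
    pattern: str,
    class_map: RelationClassMap,
    min_sources: int = 1,
    qual_min_sources: int = 1,
) -> list[DrugPath]:
    """All 4-node paths of one pattern ending at the target.

    Candidates are grown backwards from the target through class-filtered
    neighborhoods, then validated edge by edge.  Paths are deduplicated by
    node sequence; drugs directly connected to the target are excluded.
    """
    if pattern not in PATTERNS:
        raise InvalidPatternError(f"unknown pattern {pattern!r}; expected one of a, b, c")
    if not graph.has_node(target_id):
        raise MissingNodeError(target_id)
    drug_type, mid1_type, mid2_type = PATTERNS[pattern]
    paths: list[DrugPath] = []
    # Backward expansion: mid2 must touch the target, mid1 must touch both
    # mid2 and the target (qualification), the drug must touch mid1.
    for mid2 in graph.nodes_by_type(mid2_type):
        if mid2 == target_id:
            continue
        for mid1 in graph.nodes_by_type(mid1_type):
            if mid1 in (target_id, mid2):
                continue
            for drug in graph.nodes_by_type(drug_type):
                if drug in (target_id, mid1, mid2):
                    continue
                if _directly_connected(graph, drug, target_id):
                    continue
                evidence = _pattern_edges(
                    graph, pattern, drug, mid1, mid2, target_id,
                    class_map, min_sources, qual_min_sources,
                )
                if evidence is not None:
                    paths.append(
                        DrugPath(
                            pattern=pattern,
                            nodes=(drug, mid1, mid2, target_id),
                            edges=tuple(evidence),
                        )
                    )
    # Deduplicate by node sequence (parallel evidence edges already pooled).
    unique: dict[tuple, DrugPath] = {}
    for p in paths:
        unique.setdefault(p.nodes, p)
    return [unique[k] for k in sorted(unique)]


def rank_paths(
    paths: Sequence[DrugPath], graph: KnowledgeGraph, target_id: str
) -> list[DrugPath]:
    """Attach Adamic–Adar(drug, target) and sort descending; ties by (pattern, drug)."""
    scored = [
        replace(p, adamic_adar=graph.adamic_adar(p.drug_id, target_id)) for p in paths
    ]
    return sorted(scored, key=lambda p: (-p.adamic_adar, p.pattern, p.drug_id, p.nodes))


def count_unique_path_drugs(paths: Iterable[DrugPath]) -> dict[str, int]:
    """Distinct first-node drugs per pattern (all of a, b, c reported)."""
    drugs: dict[str, set[str]] = {k: set() for k in PATTERNS}
    for p in paths:
        drugs[p.pattern].add(p.drug_id)
    return {k: len(v) for k, v in drugs.items()}


def write_paths_json(paths: Sequence[DrugPath], path: str | Path) -> None:
    """Paths with nodes, evidence edges and scores as a JSON document."""
    Path(path).write_text(
        json.dumps([p.to_dict() for p in paths], indent=1), encoding="utf-8"
    )


def paths_table(paths: Sequence[DrugPath]) -> pd.DataFrame:
    """Ranked paths as a flat table (pattern, drug, mid1, mid2, target, score)."""
    return pd.DataFrame(
        [
            {
                "pattern": p.pattern,
                "drug_id": p.nodes[0],
                "mid1": p.nodes[1],
                "mid2": p.nodes[2],
                "target": p.nodes[3],
                "adamic_adar": p.adamic_adar,
            }
            for p in paths
        ],
        columns=["pattern", "drug_id", "mid1", "mid2", "target", "adamic_adar"],
    )
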