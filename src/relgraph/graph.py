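"""Property knowledge graph: construction, neighborhoods, Adamic–Adar, exports.

Nodes are normalized biomedical entities (gene / disease / chemical /
species …) with names; edges are aggregated relation triples carrying the
relation label, direction flag, number of source papers, and the mean and
sum of the contributing probabilities.  The graph is a directed multigraph;
neighborhood statistics (shared neighbors, degrees, Adamic–Adar) run on the
undirected projection with parallel edges collapsed, since "shared
neighbors" is a direction-free notion.

The Adamic–Adar score of two nodes x, y is

    A(x, y) = Σ_{u ∈ N(x) ∩ N(y)}  1 / ln |N(u)|

summed over their shared neighbors on the undirected projection; a shared
neighbor of two distinct nodes has degree ≥ 2, so every term is finite.
Higher scores mean the pair is linked through many low-degree (specific)
intermediates.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .aggregate import AggregatedTriple
from .errors import InvalidPairError, MissingNodeError

logger = logging.getLogger(__name__)

__all__ = [
    "NodeRecord",
    "KnowledgeGraph",
    "build_graph",
    "read_neo4j_import",
    "load_graph_json",
]

NODES_CSV_HEADER = "node_id:ID,name,entity_type"
EDGES_CSV_HEADER = ":START_ID,:END_ID,relation,direction,n_sources:int,prob_mean:float,prob_sum:float"


@dataclass(frozen=True)
class NodeRecord:
    """A graph node: normalized entity ID, display name, entity type."""

    node_id: str
    name: str
    entity_type: str


class KnowledgeGraph:
    """Typed property graph over aggregated relation triples.

    Thin wrapper around a :class:`networkx.MultiDiGraph` that adds the
    undirected projection, Adamic–Adar scoring, and Neo4j/JSON exports.
    """

    def __init__(self, graph: nx.MultiDiGraph | None = None, dropped_self_loops: int = 0):
        self._g = graph if graph is not None else nx.MultiDiGraph()
        self.dropped_self_loops = dropped_self_loops
        self._undirected: nx.Graph | None = None

    # -- basic accessors ----------------------------------------------------

    @property
    def digraph(self) -> nx.MultiDiGraph:
        return self._g

    @property
    def undirected(self) -> nx.Graph:
        """Undirected projection with parallel edges collapsed (cached)."""
        if self._undirected is None:
            self._undirected = nx.Graph(self._g)
        return self._undirected

    def _invalidate(self) -> None:
        self._undirected = None

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, node_id: str) -> bool:
        return self._g.has_node(node_id)

    def node_record(self, node_id: str) -> NodeRecord:
        if not self._g.has_node(node_id):
            raise MissingNodeError(node_id)
        data = self._g.nodes[node_id]
        return NodeRecord(node_id, data["name"], data["entity_type"])

    def node_records(self) -> list[NodeRecord]:
        return [self.node_record(n) for n in sorted(self._g.nodes)]

    def edge_rows(self) -> list[tuple]:
        """All edges as (start, end, relation, direction, n_sources, prob_mean, prob_sum)."""
        rows = []
        for u, v, data in self._g.edges(data=True):
            rows.append(
                (u, v, data["relation"], data["direction"], data["n_sources"],
                 data["prob_mean"], data["prob_sum"])
            )
        return sorted(rows)

    def nodes_by_type(self, entity_type: str) -> list[str]:
        return sorted(
            n for n, d in self._g.nodes(data=True) if d.get("entity_type") == entity_type
        )

    # -- construction -------------------------------------------------------

    def add_node(self, record: NodeRecord) -> None:
        self._g.add_node(record.node_id, name=record.name, entity_type=record.entity_type)
        self._invalidate()

    def add_triple(self, triple: AggregatedTriple) -> bool:
        """Add an aggregated triple as an edge; self-loops are dropped (counted)."""
        if triple.head_id == triple.tail_id:
            self.dropped_self_loops += 1
            logger.warning("dropping self-loop triple on %s (%s)", triple.head_id, triple.relation)
            return False
        self._g.add_edge(
            triple.head_id,
            triple.tail_id,
            relation=triple.relation,
            direction=triple.direction,
            n_sources=triple.n_sources,
            prob_mean=triple.prob_mean,
            prob_sum=triple.prob_sum,
        )
        self._invalidate()
        return True

    # -- neighborhood statistics --------------------------------------------

    def neighbors(
        self,
        node_id: str,
        relation_classes: "set[str] | None" = None,
        class_map: "Mapping[str, str] | None" = None,
    ) -> set[str]:
        """Undirected neighbor set, optionally restricted by relation class.

        ``class_map`` maps relation labels to class names; an edge passes the
        filter when its relation's class is in ``relation_classes``.
        """
        if not self._g.has_node(node_id):
            raise MissingNodeError(node_id)
        if relation_classes is None:
            return set(self.undirected[node_id])
        if class_map is None:
            raise InvalidPairError("relation_classes filter requires a class_map")
        out: set[str] = set()
        for u, v, data in self._g.edges(node_id, data=True):
            if class_map.get(data["relation"]) in relation_classes:
                out.add(v if u == node_id else u)
        for u, v, data in self._g.in_edges(node_id, data=True):
            if class_map.get(data["relation"]) in relation_classes:
                out.add(u if v == node_id else v)
        out.discard(node_id)
        return out

    def adamic_adar(self, x: str, y: str) -> float:
        """Adamic–Adar closeness of two distinct nodes (natural log)."""
        if x == y:
            raise InvalidPairError(f"adamic_adar requires distinct nodes, got {x!r} twice")
        und = self.undirected
        for node in (x, y):
            if not und.has_node(node):
                raise MissingNodeError(node)
        shared = set(und[x]) & set(und[y])
        # sorted summation: deterministic and exactly symmetric in (x, y)
        return sum(1.0 / math.log(und.degree(u)) for u in sorted(shared))

    # -- exports -------------------------------------------------------------

    def export_neo4j_import(self, out_dir: str | Path) -> dict[str, Path]:
        """Write nodes.csv, edges.csv and load.cypher for Neo4j bulk import.

        Headers are fixed (typed Neo4j import columns); files are UTF-8 with
        RFC-4180 quoting.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        nodes_path = out_dir / "nodes.csv"
        edges_path = out_dir / "edges.csv"
        cypher_path = out_dir / "load.cypher"

        with nodes_path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(NODES_CSV_HEADER.split(","))
            for rec in self.node_records():
                writer.writerow([rec.node_id, rec.name, rec.entity_type])

        with edges_path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(EDGES_CSV_HEADER.split(","))
            for row in self.edge_rows():
                u, v, relation, direction, n_sources, prob_mean, prob_sum = row
                writer.writerow(
                    [u, v, relation, direction, n_sources, repr(prob_mean), repr(prob_sum)]
                )

        cypher_path.write_text(_LOAD_CYPHER, encoding="utf-8")
        return {"nodes": nodes_path, "edges": edges_path, "cypher": cypher_path}

    def export_graph_json(self, path: str | Path) -> None:
        """Node-link JSON export preserving all node and edge attributes."""
        data = nx.node_link_data(self._g, edges="links")
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True), encoding="utf-8")


_LOAD_CYPHER = """\
// Bulk load for the relation knowledge graph (Neo4j 4.x).
// Place nodes.csv and edges.csv in the database import directory.
CREATE CONSTRAINT entity_id IF NOT EXISTS
FOR (e:Entity) REQUIRE e.node_id IS UNIQUE;

LOAD CSV WITH HEADERS FROM 'file:///nodes.csv' AS row
MERGE (e:Entity {node_id: row.`node_id:ID`})
SET e.name = row.name, e.entity_type = row.entity_type;

LOAD CSV WITH HEADERS FROM 'file:///edges.csv' AS row
MATCH (h:Entity {node_id: row.`:START_ID`})
MATCH (t:Entity {node_id: row.`:END_ID`})
CREATE (h)-[r:RELATION {
  relation: row.relation,
  direction: row.direction,
  n_sources: toInteger(row.`n_sources:int`),
  prob_mean: toFloat(row.`prob_mean:float`),
  prob_sum: toFloat(row.`prob_sum:float`)
}]->(t);
"""


def build_graph(
    triples: Sequence[AggregatedTriple],
    entity_table: "Mapping[str, NodeRecord] | Iterable[NodeRecord]",
) -> KnowledgeGraph:
    """Assemble the knowledge graph from aggregated triples and an entity table.

    Endpoints absent from the entity table are synthesized with entity type
    "unknown" (logged); self-loop triples are dropped with a warning count.
    Only entities referenced by at least one triple become nodes.
    """
    if not isinstance(entity_table, Mapping):
        entity_table = {rec.node_id: rec for rec in entity_table}
    kg = KnowledgeGraph()
    n_unknown = 0
    for triple in triples:
        if triple.head_id == triple.tail_id:
            kg.dropped_self_loops += 1
            logger.warning("dropping self-loop triple on %s", triple.head_id)
            continue
        for endpoint in (triple.head_id, triple.tail_id):
            if kg.has_node(endpoint):
                continue
            rec = entity_table.get(endpoint)
            if rec is None:
                rec = NodeRecord(endpoint, endpoint, "unknown")
                n_unknown += 1
            kg.add_node(rec)
        kg.add_triple(triple)
    if n_unknown:
        logger.warning("synthesized %d unknown-type nodes missing from entity table", n_unknown)
    return kg


def read_neo4j_import(in_dir: str | Path) -> KnowledgeGraph:
    """Parse nodes.csv / edges.csv written by :meth:`KnowledgeGraph.export_neo4j_import`."""
    in_dir = Path(in_dir)
    kg = KnowledgeGraph()
    with (in_dir / "nodes.csv").open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if ",".join(header) != NODES_CSV_HEADER:
            raise ValueError(f"unexpected nodes.csv header: {header}")
        for node_id, name, entity_type in reader:
            kg.add_node(NodeRecord(node_id, name, entity_type))
    with (in_dir / "edges.csv").open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if ",".join(header) != EDGES_CSV_HEADER:
            raise ValueError(f"unexpected edges.csv header: {header}")
        for u, v, relation, direction, n_sources, prob_mean, prob_sum in reader:
            kg.digraph.add_edge(
                u, v, relation=relation, direction=direction,
                n_sources=int(n_sources), prob_mean=float(prob_mean),
                prob_sum=float(prob_sum),
            )
    kg._invalidate()
    return kg


def load_graph_json(path: str | Path) -> KnowledgeGraph:
    """Inverse of :meth:`KnowledgeGraph.export_graph_json`."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    g = nx.node_link_graph(data, edges="links", multigraph=True, directed=True)
    return KnowledgeGraph(nx.MultiDiGraph(g))
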