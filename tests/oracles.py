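"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity from first principles — linear scans over
raw edge/record tables, exhaustive enumeration, hand confusion counts —
without reusing the package's indices or grouping code.
"""

from __future__ import annotations

import math

import numpy as np

from relgraph.aggregate import AggregatedTriple
from relgraph.graph import KnowledgeGraph, NodeRecord, build_graph

SYMMETRIC = {"ASSOCIATED", "DRUG_DRUG_ASSOC"}

PATTERN_TYPES = {
    "a": ("chemical", "disease", "gene"),
    "b": ("chemical", "disease", "chemical"),
    "c": ("chemical", "gene", "gene"),
}


# ---------------------------------------------------------------------------
# Adamic-Adar by brute-force shared-neighbor enumeration


def undirected_adjacency(edge_rows) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for u, v, *_ in edge_rows:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def brute_adamic_adar(graph: KnowledgeGraph, x: str, y: str) -> float:
    adj = undirected_adjacency(graph.edge_rows())
    for node in graph.node_records():
        adj.setdefault(node.node_id, set())
    shared = adj[x] & adj[y]
    return sum(1.0 / math.log(len(adj[u])) for u in shared)


# ---------------------------------------------------------------------------
# Exhaustive constrained 4-node-sequence search for drug paths


def exhaustive_drug_paths(
    graph: KnowledgeGraph,
    target: str,
    pattern: str,
    class_map,
    min_sources: int = 1,
    qual_min_sources: int = 1,
) -> set[tuple[str, str, str, str]]:
    """Enumerate every ordered typed 4-node sequence and filter by constraints."""
    rows = graph.edge_rows()
    types = {rec.node_id: rec.entity_type for rec in graph.node_records()}

    by_class: dict[tuple[str, int], set[tuple[str, str]]] = {}

    def has(u, v, cls, ms) -> bool:
        key = (cls, ms)
        if key not in by_class:
            pairs = set()
            for a, b, rel, _, ns, _, _ in rows:
                if class_map.class_of(rel).value == cls and ns >= ms:
                    pairs.add((a, b))
                    if cls in SYMMETRIC:
                        pairs.add((b, a))
            by_class[key] = pairs
        return (u, v) in by_class[key]

    linked = {frozenset((a, b)) for a, b, *_ in rows}

    drug_t, m1_t, m2_t = PATTERN_TYPES[pattern]
    nodes = sorted(types)
    found = set()
    for d in nodes:
        if types[d] != drug_t or d == target or frozenset((d, target)) in linked:
            continue
        for m1 in nodes:
            if types[m1] != m1_t or m1 in (d, target):
                continue
            for m2 in nodes:
                if types[m2] != m2_t or m2 in (d, m1, target):
                    continue
                if pattern == "a":
                    ok = (
                        has(d, m1, "TREATS", min_sources)
                        and has(m1, m2, "ASSOCIATED", min_sources)
                        and has(m2, target, "ASSOCIATED", min_sources)
                        and has(m1, target, "ASSOCIATED", qual_min_sources)
                    )
                elif pattern == "b":
                    ok = (
                        has(d, m1, "TREATS", min_sources)
                        and has(m2, m1, "TREATS", min_sources)
                        and has(m2, target, "TREATS", min_sources)
                        and has(m1, target, "ASSOCIATED", qual_min_sources)
                        and has(d, m2, "DRUG_DRUG_ASSOC", qual_min_sources)
                    )
                else:
                    ok = (
                        has(d, m1, "AFFECTS", min_sources)
                        and has(m1, m2, "ASSOCIATED", min_sources)
                        and has(m2, target, "ASSOCIATED", min_sources)
                        and has(m1, target, "ASSOCIATED", qual_min_sources)
                    )
                if ok:
                    found.add((d, m1, m2, target))
    return found


def validate_path_against_edge_table(graph: KnowledgeGraph, path) -> bool:
    """Re-check one returned path with raw edge-table scans only."""
    rows = graph.edge_rows()
    linked = {frozenset((a, b)) for a, b, *_ in rows}
    drug, mid1, _, target = path.nodes
    if frozenset((drug, target)) in linked:
        return False
    # qualification: mid1 directly linked to target
    if frozenset((mid1, target)) not in linked:
        return False
    # every evidence edge must exist in the raw table with the stated support
    table = {(a, b, rel): ns for a, b, rel, _, ns, _, _ in rows}
    for start, end, rel, ns, *_ in path.edges:
        if table.get((start, end, rel)) != ns:
            return False
    return True


# ---------------------------------------------------------------------------
# Random typed graphs


LABELS_BY_CLASS = {
    "TREATS": "may_treat",
    "AFFECTS": "affects",
    "ASSOCIATED": "associated_with",
    "DRUG_DRUG_ASSOC": "chemical_associated_with_chemical",
    "OTHER": "relation_000",
}


def random_typed_graph(
    seed: int,
    n_nodes: int = 40,
    edge_prob: float = 0.08,
    target: str = "covid",
) -> KnowledgeGraph:
    """A random graph over chemical/disease/gene nodes plus one target disease."""
    rng = np.random.default_rng(seed)
    node_types = ["chemical", "disease", "gene"]
    records = [NodeRecord(target, "target-disease", "disease")]
    for i in range(n_nodes - 1):
        t = node_types[int(rng.integers(3))]
        records.append(NodeRecord(f"n{i:03d}", f"{t}-{i}", t))
    labels = list(LABELS_BY_CLASS.values())
    triples = []
    ids = [r.node_id for r in records]
    for u in ids:
        for v in ids:
            if u == v or rng.random() >= edge_prob:
                continue
            rel = labels[int(rng.integers(len(labels)))]
            ns = int(rng.integers(1, 4))
            prob = float(rng.uniform(0.5, 1.0))
            triples.append(
                AggregatedTriple(
                    head_id=u, relation=rel, tail_id=v, direction="forward",
                    n_sources=ns, prob_mean=prob, prob_sum=prob * ns,
                    source_ids=frozenset(f"P{u}{v}{k}" for k in range(ns)),
                )
            )
    return build_graph(triples, {r.node_id: r for r in records})


# ---------------------------------------------------------------------------
# Confusion-matrix precision/recall/F1


def prf_by_confusion_counts(y_true, y_pred, labels):
    """Per-class and support-weighted P/R/F1 from raw confusion counts."""
    per = {}
    n = len(y_true)
    for c in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per[c] = (prec, rec, f1, tp + fn)
    wp = sum(s * p for p, _, _, s in per.values()) / n
    wr = sum(s * r for _, r, _, s in per.values()) / n
    wf = sum(s * f for _, _, f, s in per.values()) / n
    return per, wp, wr, wf


def pr_at_threshold(y_bin, scores, threshold):
    """Pooled precision/recall predicting positive where score >= threshold."""
    tp = fp = fn = 0
    for y, s in zip(y_bin, scores):
        pred = s >= threshold
        if pred and y:
            tp += 1
        elif pred and not y:
            fp += 1
        elif not pred and y:
            fn += 1
    prec = tp / (tp + fp) if tp + fp else 1.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return prec, rec
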