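"""Existing-drug conditions and 4-node drug-path enumeration/ranking."""

from __future__ import annotations

import json

import pytest

from oracles import exhaustive_drug_paths, random_typed_graph, validate_path_against_edge_table
from relgraph.aggregate import AggregatedTriple
from relgraph.discovery import (
    DrugPath,
    count_unique_path_drugs,
    enumerate_drug_paths,
    find_existing_drugs,
    rank_paths,
    write_paths_json,
)
from relgraph.errors import InvalidPatternError, MissingNodeError
from relgraph.graph import KnowledgeGraph, NodeRecord, build_graph
from relgraph.pipeline import bundle_to_graph, discover_drug_paths
from relgraph.synthetic import (
    DEFAULT_TARGET_ID,
    SimulationConfig,
    build_relation_labels,
    default_class_map,
    generate_prediction_records,
    inject_edge_records,
    make_planted_patterns,
    plant_drug_paths,
)

LABELS, _ = build_relation_labels(125)
CLASS_MAP = default_class_map(LABELS)
TARGET = "covid"


def tri(h, r, t, n=2, prob=0.8):
    return AggregatedTriple(
        head_id=h, relation=r, tail_id=t, direction="forward", n_sources=n,
        prob_mean=prob, prob_sum=prob * n,
        source_ids=frozenset(f"P{h}{t}{i}" for i in range(n)),
    )


def existing_drug_fixture(drop=None, weak_edge=None):
    """One drug satisfying all three conditions; ``drop``/``weak_edge`` poke holes."""
    ents = {x: NodeRecord(x, x, ty) for x, ty in [
        ("drug", "chemical"), ("gene1", "gene"), ("dis1", "disease"), (TARGET, "disease"),
        ("bystander", "chemical"),
    ]}
    edges = {
        "affects": ("drug", "affects", "gene1"),
        "gene_assoc": ("gene1", "associated_with", TARGET),
        "treats": ("drug", "may_treat", "dis1"),
        "dis_assoc": ("dis1", "associated_with", TARGET),
    }
    triples = []
    for name, (h, r, t) in edges.items():
        if name == drop:
            continue
        triples.append(tri(h, r, t, n=1 if name == weak_edge else 2))
    triples.append(tri("bystander", "may_treat", "dis1"))  # lacks gene evidence
    return build_graph(triples, ents)


class TestFindExistingDrugs:
    def test_empty_graph_gives_empty_table(self):
        assert find_existing_drugs(KnowledgeGraph(), TARGET, CLASS_MAP) == []

    def test_missing_target_rejected(self):
        g = build_graph([tri("a", "may_treat", "b")], {})
        with pytest.raises(MissingNodeError):
            find_existing_drugs(g, "ghost", CLASS_MAP)

    def test_exactly_the_qualifying_drug_is_returned(self):
        hits = find_existing_drugs(existing_drug_fixture(), TARGET, CLASS_MAP)
        assert [h.drug_id for h in hits] == ["drug"]
        assert hits[0].gene_evidence and hits[0].disease_evidence

    @pytest.mark.parametrize("drop", ["affects", "gene_assoc", "treats", "dis_assoc"])
    def test_removing_any_evidence_edge_removes_the_hit(self, drop):
        hits = find_existing_drugs(existing_drug_fixture(drop=drop), TARGET, CLASS_MAP)
        assert hits == []

    @pytest.mark.parametrize("weak", ["affects", "gene_assoc", "treats", "dis_assoc"])
    def test_min_sources_enforced_per_edge(self, weak):
        g = existing_drug_fixture(weak_edge=weak)
        assert find_existing_drugs(g, TARGET, CLASS_MAP, min_sources=2) == []
        assert [h.drug_id for h in find_existing_drugs(g, TARGET, CLASS_MAP, min_sources=1)] == ["drug"]

    def test_hits_ranked_by_adamic_adar(self):
        g = random_typed_graph(seed=10, n_nodes=40, edge_prob=0.2)
        hits = find_existing_drugs(g, TARGET, CLASS_MAP, min_sources=1)
        scores = [h.adamic_adar for h in hits]
        assert scores == sorted(scores, reverse=True)
        for h in hits:
            assert h.adamic_adar == pytest.approx(g.adamic_adar(h.drug_id, TARGET))


class TestEnumerateDrugPaths:
    def test_missing_target_rejected(self):
        g = build_graph([tri("a", "may_treat", "b")], {})
        with pytest.raises(MissingNodeError):
            enumerate_drug_paths(g, "ghost", "a", CLASS_MAP)

    def test_unknown_pattern_rejected(self):
        g = random_typed_graph(seed=1, n_nodes=10)
        with pytest.raises(InvalidPatternError):
            enumerate_drug_paths(g, TARGET, "z", CLASS_MAP)

    @pytest.mark.parametrize("pattern", ["a", "b", "c"])
    def test_matches_exhaustive_search_on_random_graphs(self, pattern):
        for seed in range(5):
            g = random_typed_graph(seed=100 + seed, n_nodes=35, edge_prob=0.12)
            got = {p.nodes for p in enumerate_drug_paths(g, TARGET, pattern, CLASS_MAP)}
            assert got == exhaustive_drug_paths(g, TARGET, pattern, CLASS_MAP)

    def test_planted_paths_recovered_and_decoys_excluded(self, small_bundle):
        patterns = make_planted_patterns("a", 5)
        bundle = plant_drug_paths(small_bundle, patterns, seed=21)
        # decoy 1: pattern-a shape missing the mid1->target qualification edge
        # decoy 2: complete pattern-a shape but drug directly linked to target
        decoys = [
            ("C7000000", "may_treat", "C7000001"),
            ("C7000001", "associated_with", "C7000002"),
            ("C7000002", "associated_with", DEFAULT_TARGET_ID),
            ("C7100000", "may_treat", "C7100001"),
            ("C7100001", "associated_with", "C7100002"),
            ("C7100002", "associated_with", DEFAULT_TARGET_ID),
            ("C7100001", "associated_with", DEFAULT_TARGET_ID),
            ("C7100000", "associated_with", DEFAULT_TARGET_ID),  # direct drug-target link
            ("C7200000", "affects", "C7200001"),  # wrong class for pattern a step 1
            ("C7200001", "associated_with", "C7200002"),
            ("C7200002", "associated_with", DEFAULT_TARGET_ID),
            ("C7200001", "associated_with", DEFAULT_TARGET_ID),
        ]
        node_types = {
            "C7000000": "chemical", "C7000001": "disease", "C7000002": "gene",
            "C7100000": "chemical", "C7100001": "disease", "C7100002": "gene",
            "C7200000": "chemical", "C7200001": "disease", "C7200002": "gene",
        }
        bundle = inject_edge_records(bundle, decoys, seed=22, node_types=node_types)
        g = bundle_to_graph(bundle)
        paths = enumerate_drug_paths(g, DEFAULT_TARGET_ID, "a", bundle.class_map)
        drugs = {p.drug_id for p in paths}
        assert drugs == {p.drug_id for p in patterns}
        assert len(drugs) == 5

    def test_direct_target_link_excludes_planted_pattern_b_drug(self, small_bundle):
        (pattern,) = make_planted_patterns("b", 1)
        bundle = plant_drug_paths(small_bundle, [pattern], seed=31)
        g = bundle_to_graph(bundle)
        assert {p.drug_id for p in enumerate_drug_paths(g, DEFAULT_TARGET_ID, "b", bundle.class_map)} == {
            pattern.drug_id
        }
        linked = inject_edge_records(
            bundle, [(pattern.drug_id, "associated_with", DEFAULT_TARGET_ID)], seed=32
        )
        g2 = bundle_to_graph(linked)
        assert pattern.drug_id not in {
            p.drug_id for p in enumerate_drug_paths(g2, DEFAULT_TARGET_ID, "b", linked.class_map)
        }

    def test_exclusion_is_monotone(self):
        """Adding a direct drug-target edge never creates new paths for that drug."""
        g = random_typed_graph(seed=16, n_nodes=45, edge_prob=0.25)
        before = {p.nodes for p in enumerate_drug_paths(g, TARGET, "a", CLASS_MAP)}
        drugs = {p[0] for p in before}
        assert drugs, "fixture graph must contain at least one path"
        victim = sorted(drugs)[0]
        g.add_triple(tri(victim, "associated_with", TARGET))
        after = {p.nodes for p in enumerate_drug_paths(g, TARGET, "a", CLASS_MAP)}
        assert after == {p for p in before if p[0] != victim}

    def test_every_returned_path_revalidates_against_raw_edges(self, planted_bundle, planted_graph):
        for pattern in "abc":
            for path in enumerate_drug_paths(
                planted_graph, DEFAULT_TARGET_ID, pattern, planted_bundle.class_map
            ):
                assert validate_path_against_edge_table(planted_graph, path)


class TestRankingAndCounts:
    def test_single_path_gets_score_attached(self):
        g = build_graph(
            [tri("a", "r", "b"), tri("b", "r", TARGET)],
            {TARGET: NodeRecord(TARGET, TARGET, "disease")},
        )
        p = DrugPath(pattern="a", nodes=("a", "b", "x", TARGET), edges=())
        (ranked,) = rank_paths([p], g, TARGET)
        assert ranked.adamic_adar == pytest.approx(g.adamic_adar("a", TARGET))

    def test_forced_order_by_score(self):
        g = build_graph(
            [tri("hi", "r", "mid"), tri("mid", "r", TARGET), tri("lo", "r", "other")],
            {TARGET: NodeRecord(TARGET, TARGET, "disease")},
        )
        paths = [
            DrugPath(pattern="a", nodes=("lo", "x", "y", TARGET), edges=()),
            DrugPath(pattern="a", nodes=("hi", "x", "y", TARGET), edges=()),
        ]
        ranked = rank_paths(paths, g, TARGET)
        assert [p.drug_id for p in ranked] == ["hi", "lo"]

    def test_twenty_path_fixture_matches_sort_oracle(self):
        g = random_typed_graph(seed=77, n_nodes=45, edge_prob=0.2)
        chems = g.nodes_by_type("chemical")[:20]
        paths = [DrugPath(pattern="a", nodes=(c, "m1", "m2", TARGET), edges=()) for c in chems]
        ranked = rank_paths(paths, g, TARGET)
        oracle = sorted(chems, key=lambda c: (-g.adamic_adar(c, TARGET), "a", c))
        assert [p.drug_id for p in ranked] == oracle

    def test_unique_drug_counts(self, planted_bundle, planted_graph):
        ranked, counts = discover_drug_paths(
            planted_graph, DEFAULT_TARGET_ID, class_map=planted_bundle.class_map
        )
        truth = {
            k: len({p.drug_id for p in planted_bundle.planted if p.pattern == k})
            for k in "abc"
        }
        assert counts == truth == {"a": 5, "b": 3, "c": 2}

    def test_empty_and_dedup_counts(self):
        assert count_unique_path_drugs([]) == {"a": 0, "b": 0, "c": 0}
        paths = [
            DrugPath(pattern="a", nodes=("d", f"m{i}", "x", TARGET), edges=()) for i in range(3)
        ]
        assert count_unique_path_drugs(paths)["a"] == 1

    def test_paths_json_is_readable(self, tmp_path):
        p = DrugPath(pattern="c", nodes=("d", "g1", "g2", TARGET),
                     edges=(("d", "g1", "affects", 2, 0.9, 1.8),), adamic_adar=1.44)
        out = tmp_path / "paths.json"
        write_paths_json([p], out)
        payload = json.loads(out.read_text())
        assert payload[0]["pattern"] == "c"
        assert payload[0]["nodes"] == ["d", "g1", "g2", TARGET]
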