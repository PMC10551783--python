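"""Triple merging, direction canonicalization and credibility filters."""

from __future__ import annotations

import random
from datetime import date

import pytest

from relgraph.aggregate import (
    AggregatedTriple,
    CredibilityRules,
    InversePairMap,
    RelationPrediction,
    aggregate_predictions,
    aggregate_triples,
    canonicalize_direction,
    drop_non_relations,
    filter_attention_above_mean,
    filter_conclusive,
    filter_date_window,
    rank_drugs_by_prob_sum,
    read_predictions_jsonl,
    read_predictions_tsv,
    write_predictions_jsonl,
    write_predictions_tsv,
)
from relgraph.errors import ConfigurationError, InvalidInputError, UnknownRelationError
from relgraph.evaluate import NOT_A_RELATION

PAIR_MAP = InversePairMap.from_pairs(
    [("may_treat", "may_be_treated_by")], symmetric=["associated_with"]
)


def rec(
    head="C1",
    rel="may_treat",
    tail="C2",
    paper="P1",
    prob=0.9,
    sent="We demonstrate an effect.",
    day="2022-07-01",
    attention=5.0,
    topic="treatment",
    sid=None,
):
    return RelationPrediction(
        paper_id=paper,
        sentence_id=sid or f"{paper}:{random.randrange(10**6)}",
        sentence=sent,
        head_id=head,
        head_name=head,
        head_type="chemical",
        tail_id=tail,
        tail_name=tail,
        tail_type="disease",
        relation=rel,
        probability=prob,
        topic=topic,
        date=day,
        attention_score=attention,
    )


class TestInversePairMap:
    def test_involution_enforced(self):
        with pytest.raises(ConfigurationError):
            InversePairMap({"a": ("b", True), "b": ("c", False), "c": ("b", True)})

    def test_exactly_one_canonical_per_pair(self):
        with pytest.raises(ConfigurationError):
            InversePairMap({"a": ("b", True), "b": ("a", True)})

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "pairs.yaml"
        PAIR_MAP.to_yaml(path)
        loaded = InversePairMap.from_yaml(path)
        assert loaded.inverse("may_treat") == "may_be_treated_by"
        assert loaded.is_canonical("may_treat") and not loaded.is_canonical("may_be_treated_by")
        assert loaded.inverse("associated_with") == "associated_with"


class TestDropNonRelations:
    def test_all_null_removed(self):
        assert drop_non_relations([rec(rel=NOT_A_RELATION)] * 3) == []

    def test_no_null_is_identity(self):
        records = [rec(sid="P1:1"), rec(sid="P1:2")]
        assert drop_non_relations(records) == records

    def test_mixed_fixture_matches_linear_scan(self):
        records = [rec(rel=NOT_A_RELATION if i % 3 == 0 else "may_treat", sid=f"P1:{i}") for i in range(10)]
        survivors = drop_non_relations(records)
        assert len(survivors) == sum(1 for r in records if r.relation != NOT_A_RELATION) == 6
        assert survivors == [r for r in records if r.relation != NOT_A_RELATION]


class TestCanonicalizeDirection:
    def test_inverse_label_swaps_endpoints(self):
        out = canonicalize_direction(rec(head="B", rel="may_be_treated_by", tail="A"), PAIR_MAP)
        assert (out.head_id, out.relation, out.tail_id) == ("A", "may_treat", "B")

    def test_canonical_record_returned_unchanged(self):
        r = rec()
        assert canonicalize_direction(r, PAIR_MAP) is r

    def test_idempotent(self):
        r = rec(head="B", rel="may_be_treated_by", tail="A")
        once = canonicalize_direction(r, PAIR_MAP)
        assert canonicalize_direction(once, PAIR_MAP) is once

    def test_unknown_relation_strict_vs_lenient(self):
        r = rec(rel="mystery_relation")
        assert canonicalize_direction(r, PAIR_MAP) is r
        with pytest.raises(UnknownRelationError):
            canonicalize_direction(r, PAIR_MAP, strict=True)


class TestAggregateTriples:
    def test_singleton(self):
        (t,) = aggregate_triples([rec(prob=0.9)])
        assert (t.n_sources, t.prob_mean, t.prob_sum) == (1, 0.9, 0.9)

    def test_two_papers_mean_and_sum(self):
        (t,) = aggregate_triples([rec(paper="P1", prob=0.8), rec(paper="P2", prob=0.6)])
        assert t.n_sources == 2
        assert t.prob_mean == pytest.approx(0.7)
        assert t.prob_sum == pytest.approx(1.4)
        assert t.source_ids == frozenset({"P1", "P2"})

    def test_same_paper_twice_counts_one_source(self):
        (t,) = aggregate_triples([rec(paper="P1", prob=0.8), rec(paper="P1", prob=0.6)])
        assert t.n_sources == 1
        assert t.prob_mean == pytest.approx(0.7)
        assert t.prob_sum == pytest.approx(1.4)

    def test_conservation_and_permutation_invariance(self, small_bundle):
        records = drop_non_relations(list(small_bundle.predictions))
        triples = aggregate_triples(records)
        assert sum(t.prob_sum for t in triples) == pytest.approx(
            sum(r.probability for r in records)
        )
        shuffled = records[:]
        random.Random(0).shuffle(shuffled)
        assert aggregate_triples(shuffled) == triples

    def test_canonicalize_commutes_with_aggregation(self):
        records = [
            rec(head="B", rel="may_be_treated_by", tail="A", paper="P1", prob=0.8, sid="P1:0"),
            rec(head="A", rel="may_treat", tail="B", paper="P2", prob=0.6, sid="P2:0"),
        ]
        pre = [canonicalize_direction(r, PAIR_MAP) for r in records]
        assert aggregate_triples(pre) == aggregate_triples(
            [canonicalize_direction(r, PAIR_MAP) for r in pre]
        )

    def test_pipeline_marks_collapsed_direction(self):
        records = [
            rec(head="B", rel="may_be_treated_by", tail="A", paper="P1", sid="P1:0"),
            rec(head="C", rel="may_treat", tail="D", paper="P1", sid="P1:1"),
            rec(rel=NOT_A_RELATION, head="E", tail="F", sid="P1:2"),
        ]
        triples = aggregate_predictions(records, PAIR_MAP)
        by_key = {(t.head_id, t.relation, t.tail_id): t for t in triples}
        assert by_key[("A", "may_treat", "B")].direction == "inverse-collapsed"
        assert by_key[("C", "may_treat", "D")].direction == "forward"
        assert ("E", NOT_A_RELATION, "F") not in by_key


class TestDateWindow:
    WINDOW = (date(2022, 6, 1), date(2023, 6, 1))

    def test_boundary_dates_inclusive(self):
        assert filter_date_window([rec(day="2022-06-01")], self.WINDOW)
        assert filter_date_window([rec(day="2023-06-01")], self.WINDOW)

    def test_all_outside_gives_empty(self):
        assert filter_date_window([rec(day="2020-01-01"), rec(day="2024-01-01")], self.WINDOW) == []

    def test_mixed_fixture_matches_scan(self):
        days = [f"20{y}-0{m}-15" for y in (20, 22, 23) for m in range(1, 8)]
        records = [rec(day=d, sid=f"P1:{i}") for i, d in enumerate(days)]
        kept = filter_date_window(records, self.WINDOW)
        assert kept == [r for r in records if self.WINDOW[0] <= r.date <= self.WINDOW[1]]


class TestAttentionFilter:
    def test_equal_scores_keep_nothing(self):
        scores = {"P1": 2.0, "P2": 2.0}
        assert filter_attention_above_mean([rec(paper="P1"), rec(paper="P2")], scores) == []

    def test_two_point_mean(self):
        scores = {"P1": 1.0, "P2": 3.0}
        kept = filter_attention_above_mean([rec(paper="P1"), rec(paper="P2")], scores)
        assert [r.paper_id for r in kept] == ["P2"]

    def test_hundred_paper_fixture_matches_oracle(self):
        rng = random.Random(4)
        scores = {f"P{i}": rng.uniform(0, 10) for i in range(100)}
        records = [rec(paper=f"P{i}", sid=f"P{i}:0") for i in range(100)]
        mean = sum(scores.values()) / len(scores)
        kept = filter_attention_above_mean(records, scores)
        assert {r.paper_id for r in kept} == {p for p, s in scores.items() if s > mean}

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidInputError):
            filter_attention_above_mean([rec()], {})


class TestConclusiveFilter:
    RULES = CredibilityRules(conclusive_keywords=("demonstrate", "effective"))

    def test_direct_match_kept(self):
        assert filter_conclusive([rec(sent="We demonstrate that X helps.")], self.RULES)

    def test_word_boundary_blocks_substring(self):
        assert filter_conclusive([rec(sent="A note on cost-ineffectiveness.")], self.RULES) == []

    def test_case_insensitive_and_stemmed(self):
        assert filter_conclusive([rec(sent="This DEMONSTRATED efficacy.")], self.RULES)

    def test_twenty_sentence_fixture_matches_regex_oracle(self):
        import re

        sentences = [
            f"Sentence {i}: treatment was {'effective' if i % 4 == 0 else 'studied'} "
            f"and results {'demonstrate' if i % 5 == 0 else 'describe'} benefit."
            for i in range(20)
        ]
        records = [rec(sent=s, sid=f"P1:{i}") for i, s in enumerate(sentences)]
        kept = filter_conclusive(records, self.RULES)
        oracle = re.compile(r"\b(demonstrate|effective)", re.I)
        assert [r.sentence for r in kept] == [s for s in sentences if oracle.search(s)]

    def test_empty_keyword_set_rejected(self):
        with pytest.raises(ConfigurationError):
            CredibilityRules(conclusive_keywords=())


class TestRankDrugsByProbSum:
    @staticmethod
    def triple(drug, rel="may_treat", target="COVID", prob_sum=1.0, n=2):
        return AggregatedTriple(
            head_id=drug, relation=rel, tail_id=target, direction="forward",
            n_sources=n, prob_mean=prob_sum / n, prob_sum=prob_sum,
            source_ids=frozenset(f"P{i}{drug}" for i in range(n)),
        )

    def test_singleton(self):
        df = rank_drugs_by_prob_sum([self.triple("D1", prob_sum=1.6)], ["may_treat"], "COVID")
        assert list(df["drug_id"]) == ["D1"]
        assert df["score"].iloc[0] == pytest.approx(1.6)

    def test_tie_broken_lexicographically(self):
        df = rank_drugs_by_prob_sum(
            [self.triple("Dz"), self.triple("Da")], ["may_treat"], "COVID"
        )
        assert list(df["drug_id"]) == ["Da", "Dz"]

    def test_ten_drug_fixture_matches_sort_oracle(self):
        rng = random.Random(9)
        triples = [self.triple(f"D{i}", prob_sum=round(rng.uniform(0.5, 5), 3)) for i in range(10)]
        triples.append(self.triple("D0", prob_sum=1.0))  # second triple for D0
        df = rank_drugs_by_prob_sum(triples, ["may_treat"], "COVID")
        scores = {}
        for t in triples:
            scores[t.head_id] = scores.get(t.head_id, 0.0) + t.prob_sum
        oracle = sorted(scores, key=lambda d: (-scores[d], d))
        assert list(df["drug_id"]) == oracle

    def test_missing_target_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="absent"):
            df = rank_drugs_by_prob_sum([self.triple("D1")], ["may_treat"], "NOPE")
        assert df.empty


def test_prediction_io_round_trips(small_bundle, tmp_path):
    records = list(small_bundle.predictions[:25])
    jl, tsv = tmp_path / "p.jsonl", tmp_path / "p.tsv"
    write_predictions_jsonl(records, jl)
    write_predictions_tsv(records, tsv)
    assert read_predictions_jsonl(jl) == records
    assert read_predictions_tsv(tsv) == records
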