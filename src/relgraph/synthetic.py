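"""Seeded synthetic relation-extraction corpora with planted drug paths.

Real inputs to this pipeline are sentence-level relation predictions from a
classifier run over a topical literature corpus, joined against UMLS
semantic-type tables.  This module emulates those inputs end to end so that
every downstream stage — annotation, aggregation, graph construction,
drug-path discovery, topic analytics — is testable without any download:

* a 125-label relation vocabulary ("not a relation" at index 0) with
  inverse-direction label pairs and a default coarse class map,
* typed entities (gene / disease / chemical / species) with synthetic
  CUIs in UMLS surface form ("C" + 7 digits),
* per-paper metadata (publication date, attention score, one of the eight
  LitCovid topics) and per-record softmax-like confidences,
* graphs with *planted* pattern-a/b/c drug paths whose ground truth is
  recorded for recovery tests.

Everything is driven by a single integer seed; identical configurations
produce byte-identical serialized bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import (
    InversePairMap,
    RelationPrediction,
    write_predictions_jsonl,
    write_predictions_tsv,
)
from .discovery import PATTERNS, RelationClass, RelationClassMap
from .errors import ConfigurationError, PlantingConflictError
from .evaluate import NOT_A_RELATION
from .semantics import SemanticTypeRecord, write_semantic_table

__all__ = [
    "LITCOVID_TOPICS",
    "DEFAULT_TARGET_ID",
    "DEFAULT_TARGET_NAME",
    "SimulationConfig",
    "PlantedPattern",
    "SyntheticBundle",
    "build_relation_labels",
    "default_class_map",
    "generate_semantic_table",
    "generate_prediction_records",
    "plant_drug_paths",
    "make_planted_patterns",
    "inject_edge_records",
]

#: The eight curated LitCovid article topics.
LITCOVID_TOPICS = (
    "general information",
    "mechanism",
    "transmission",
    "diagnosis",
    "treatment",
    "prevention",
    "case report",
    "epidemic forecasting",
)

#: Synthetic target disease node (the UMLS CUI for COVID-19).
DEFAULT_TARGET_ID = "C5203670"
DEFAULT_TARGET_NAME = "COVID-19"

#: Semantic-type metadata per synthetic entity type: (name, code, group, abbr).
_TYPE_INFO = {
    "gene": ("Gene or Genome", "T028", "Genes & Molecular Sequences", "GENE"),
    "disease": ("Disease or Syndrome", "T047", "Disorders", "DISO"),
    "chemical": ("Pharmacologic Substance", "T121", "Chemicals & Drugs", "CHEM"),
    "species": ("Virus", "T005", "Living Beings", "LIVB"),
}

#: Canonical labels used to realize planted edges, per edge class.
_CLASS_LABEL = {
    RelationClass.TREATS: "may_treat",
    RelationClass.AFFECTS: "affects",
    RelationClass.ASSOCIATED: "associated_with",
    RelationClass.DRUG_DRUG_ASSOC: "chemical_associated_with_chemical",
}

_NAMED_PAIRS = (
    ("may_treat", "may_be_treated_by"),
    ("affects", "affected_by"),
    ("may_prevent", "may_be_prevented_by"),
    ("gene_associated_with_disease", "disease_has_associated_gene"),
    ("causes", "caused_by"),
)
_NAMED_SYMMETRIC = ("associated_with", "chemical_associated_with_chemical", "interacts_with")


def build_relation_labels(n_labels: int = 125) -> tuple[list[str], InversePairMap]:
    """The relation vocabulary: null label first, then inverse-paired labels.

    A handful of labels carry field-standard names (may_treat /
    may_be_treated_by, affects / affected_by, association labels); the
    remainder are generic ``relation_k`` / ``inverse_of_relation_k`` pairs,
    with one trailing symmetric label when the count is odd.
    """
    if n_labels < 2:
        raise ConfigurationError("need at least 2 relation labels (null + 1)")
    labels = [NOT_A_RELATION]
    pairs: list[tuple[str, str]] = []
    symmetric: list[str] = []
    for fwd, inv in _NAMED_PAIRS:
        if len(labels) + 2 > n_labels:
            break
        labels.extend([fwd, inv])
        pairs.append((fwd, inv))
    for sym in _NAMED_SYMMETRIC:
        if len(labels) + 1 > n_labels:
            break
        labels.append(sym)
        symmetric.append(sym)
    k = 0
    while len(labels) < n_labels:
        if n_labels - len(labels) >= 2:
            fwd, inv = f"relation_{k:03d}", f"inverse_of_relation_{k:03d}"
            labels.extend([fwd, inv])
            pairs.append((fwd, inv))
        else:
            labels.append(f"co_occurs_with_{k:03d}")
            symmetric.append(f"co_occurs_with_{k:03d}")
        k += 1
    return labels, InversePairMap.from_pairs(pairs, symmetric)


def default_class_map(labels: Sequence[str]) -> RelationClassMap:
    """Coarse edge-class assignment for the synthetic vocabulary."""
    mapping: dict[str, str] = {}
    for lab in labels:
        if lab in ("may_treat", "may_be_treated_by"):
            mapping[lab] = RelationClass.TREATS.value
        elif lab in ("affects", "affected_by"):
            mapping[lab] = RelationClass.AFFECTS.value
        elif lab == "chemical_associated_with_chemical":
            mapping[lab] = RelationClass.DRUG_DRUG_ASSOC.value
        elif "associated" in lab:
            mapping[lab] = RelationClass.ASSOCIATED.value
        else:
            mapping[lab] = RelationClass.OTHER.value
    return RelationClassMap(mapping)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic corpus.

    Defaults emulate the shape of a topical-literature relation-extraction
    run: 125 relation labels including the null label, eight article
    topics, softmax-like confidences from a Beta(c, 1) distribution, and
    heavy-tailed lognormal attention scores.
    """

    n_papers: int = 200
    n_entities: int = 300
    entity_type_weights: Mapping[str, float] = field(
        default_factory=lambda: {"gene": 0.30, "disease": 0.25, "chemical": 0.30, "species": 0.15}
    )
    n_relation_labels: int = 125
    inverse_pair_fraction: float = 0.2
    not_a_relation_rate: float = 0.30
    topics: tuple[str, ...] = LITCOVID_TOPICS
    date_range: tuple[date, date] = (date(2020, 1, 1), date(2023, 6, 1))
    attention_score_distribution: tuple[float, float] = (1.0, 1.0)  # lognormal (mu, sigma)
    probability_concentration: float = 4.0
    mean_sentences_per_paper: float = 12.0
    topic_tilt: "Mapping[str, Mapping[str, float]] | None" = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_papers < 0 or self.n_entities < 2:
            raise ConfigurationError("need n_papers >= 0 and n_entities >= 2")
        if abs(sum(self.entity_type_weights.values()) - 1.0) > 1e-9:
            raise ConfigurationError("entity_type_weights must sum to 1")
        if any(w < 0 for w in self.entity_type_weights.values()):
            raise ConfigurationError("entity_type_weights must be nonnegative")
        if self.n_relation_labels < 2:
            raise ConfigurationError("n_relation_labels must be >= 2")
        if not (0.0 <= self.inverse_pair_fraction <= 1.0):
            raise ConfigurationError("inverse_pair_fraction must lie in [0, 1]")
        if not (0.0 <= self.not_a_relation_rate < 1.0):
            raise ConfigurationError("not_a_relation_rate must lie in [0, 1)")
        if self.date_range[0] > self.date_range[1]:
            raise ConfigurationError("date_range start must not exceed end")
        if self.probability_concentration <= 0:
            raise ConfigurationError("probability_concentration must be positive")
        if not self.topics:
            raise ConfigurationError("topics must be non-empty")


@dataclass(frozen=True)
class PlantedPattern:
    """Ground truth for one planted drug path (pattern a, b or c)."""

    pattern: str
    node_ids: tuple[str, str, str, str]  # (drug, mid1, mid2, target)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ConfigurationError(f"unknown pattern {self.pattern!r}")
        if len(self.node_ids) != 4 or len(set(self.node_ids)) != 4:
            raise ConfigurationError("node_ids must be 4 distinct identifiers")

    @property
    def drug_id(self) -> str:
        return self.node_ids[0]

    @property
    def target_id(self) -> str:
        return self.node_ids[3]

    def required_edges(self) -> list[tuple[str, RelationClass, str]]:
        """Template plus qualification edges as (head, class, tail) rows."""
        drug, mid1, mid2, target = self.node_ids
        if self.pattern == "a":
            return [
                (drug, RelationClass.TREATS, mid1),
                (mid1, RelationClass.ASSOCIATED, mid2),
                (mid2, RelationClass.ASSOCIATED, target),
                (mid1, RelationClass.ASSOCIATED, target),
            ]
        if self.pattern == "b":
            return [
                (drug, RelationClass.TREATS, mid1),
                (mid2, RelationClass.TREATS, mid1),
                (mid2, RelationClass.TREATS, target),
                (mid1, RelationClass.ASSOCIATED, target),
                (drug, RelationClass.DRUG_DRUG_ASSOC, mid2),
            ]
        return [
            (drug, RelationClass.AFFECTS, mid1),
            (mid1, RelationClass.ASSOCIATED, mid2),
            (mid2, RelationClass.ASSOCIATED, target),
            (mid1, RelationClass.ASSOCIATED, target),
        ]

    def node_types(self) -> dict[str, str]:
        drug_t, mid1_t, mid2_t = PATTERNS[self.pattern]
        return {
            self.node_ids[0]: drug_t,
            self.node_ids[1]: mid1_t,
            self.node_ids[2]: mid2_t,
            self.node_ids[3]: "disease",
        }


@dataclass(frozen=True)
class SyntheticBundle:
    """A complete synthetic corpus: predictions, tables, ground truth."""

    predictions: tuple[RelationPrediction, ...]
    semantic_table: Mapping[str, SemanticTypeRecord]
    entities: Mapping[str, "tuple[str, str]"]  # id -> (name, entity_type)
    planted: tuple[PlantedPattern, ...]
    paper_metadata: "pd.DataFrame"
    labels: tuple[str, ...]
    inverse_map: InversePairMap
    class_map: RelationClassMap
    provenance: tuple[str, ...] = ()

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Serialize the bundle: predictions (JSONL + TSV), semantic TSV,
        metadata CSV, and a column-schema file."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files = {
            "predictions_jsonl": out_dir / "predictions.jsonl",
            "predictions_tsv": out_dir / "predictions.tsv",
            "semantic_tsv": out_dir / "semantic_types.tsv",
            "metadata_csv": out_dir / "paper_metadata.csv",
            "schema": out_dir / "SCHEMA.md",
        }
        write_predictions_jsonl(self.predictions, files["predictions_jsonl"])
        write_predictions_tsv(self.predictions, files["predictions_tsv"])
        write_semantic_table(self.semantic_table.values(), files["semantic_tsv"])
        self.paper_metadata.to_csv(files["metadata_csv"], index=False)
        files["schema"].write_text(_SCHEMA_DOC, encoding="utf-8")
        return files


_SCHEMA_DOC = """\
# Synthetic corpus file schema

## predictions.jsonl / predictions.tsv
One sentence-level relation prediction per row.
Columns: paper_id, sentence_id, sentence, head_id, head_name, head_type,
tail_id, tail_name, tail_type, relation, probability, topic, date
(ISO YYYY-MM-DD), attention_score.

## semantic_types.tsv
CUI-keyed semantic-type table. Columns: cui, type_name, type_code,
group_name, group_abbr.

## paper_metadata.csv
One row per source paper. Columns: paper_id, date (ISO), attention_score,
topic, n_sentences (number of emitted prediction records).
"""


def generate_semantic_table(
    n_types: int, n_groups: int, seed: int
) -> list[SemanticTypeRecord]:
    """A synthetic UMLS-style table: ``n_types`` typed CUIs over ``n_groups`` groups.

    Each type belongs to exactly one group, every group is non-empty, and
    codes/abbreviations are unique.  Deterministic for a given seed.
    """
    if not (1 <= n_groups <= n_types):
        raise ConfigurationError(
            f"need 1 <= n_groups <= n_types, got n_groups={n_groups}, n_types={n_types}"
        )
    rng = np.random.default_rng(seed)
    group_of = np.concatenate(
        [np.arange(n_groups), rng.integers(0, n_groups, size=n_types - n_groups)]
    )
    rng.shuffle(group_of)
    # reindex so that every group still appears (shuffle preserves multiset)
    records = []
    for i in range(n_types):
        g = int(group_of[i])
        records.append(
            SemanticTypeRecord(
                cui=f"C9{i + 1:06d}",
                type_name=f"Semantic Type {i + 1:03d}",
                type_code=f"T{i + 1:03d}",
                group_name=f"Semantic Group {g + 1:02d}",
                group_abbr=f"G{g + 1:02d}",
            )
        )
    return records


def _entity_semantic_record(entity_id: str, entity_type: str) -> SemanticTypeRecord:
    name, code, group, abbr = _TYPE_INFO[entity_type]
    return SemanticTypeRecord(
        cui=entity_id, type_name=name, type_code=code, group_name=group, group_abbr=abbr
    )


_SENTENCE_TEMPLATES = (
    "We demonstrate that {head} {rel} {tail} in patients.",
    "Results show that {head} {rel} {tail}.",
    "This study suggests {head} {rel} {tail} under specific conditions.",
    "It was observed that {head} {rel} {tail} in the cohort.",
    "Analysis indicated that {head} {rel} {tail}.",
)


def _make_sentence(rng: np.random.Generator, head: str, relation: str, tail: str) -> str:
    template = _SENTENCE_TEMPLATES[int(rng.integers(len(_SENTENCE_TEMPLATES)))]
    rel_words = relation.replace("_", " ")
    return template.format(head=head, rel=rel_words, tail=tail)


def _draw_probability(rng: np.random.Generator, concentration: float) -> float:
    """Beta(c, 1) confidence: mass concentrates near 1 as c grows, like a
    well-calibrated softmax winner.  Clipped into (0, 1]."""
    return float(min(max(rng.beta(concentration, 1.0), 1e-9), 1.0))


def generate_prediction_records(config: SimulationConfig) -> SyntheticBundle:
    """Generate a full synthetic prediction corpus from a configuration.

    Per paper the sentence count is Poisson(mean_sentences_per_paper); each
    record draws head/tail entities, a relation label (the null label at the
    configured rate, optionally tilted per topic), and a confidence.  For a
    configured fraction of non-null records the inverse-direction mirror
    record is also emitted.
    """
    rng = np.random.default_rng(config.seed)
    labels, inverse_map = build_relation_labels(config.n_relation_labels)
    class_map = default_class_map(labels)
    non_null = labels[1:]

    etypes = sorted(config.entity_type_weights)
    eweights = np.array([config.entity_type_weights[t] for t in etypes])
    entities: dict[str, tuple[str, str]] = {}
    semantic_table: dict[str, SemanticTypeRecord] = {}
    for i in range(config.n_entities):
        eid = f"C{i + 1:07d}"
        etype = etypes[int(rng.choice(len(etypes), p=eweights))]
        name = f"{etype}_{i + 1:04d}"
        entities[eid] = (name, etype)
        semantic_table[eid] = _entity_semantic_record(eid, etype)
    entity_ids = list(entities)

    start, end = config.date_range
    span_days = (end - start).days
    papers = []
    for p in range(config.n_papers):
        papers.append(
            {
                "paper_id": f"PMID{p + 1:08d}",
                "date": (start + timedelta(days=int(rng.integers(span_days + 1)))).isoformat(),
                "attention_score": float(
                    rng.lognormal(*config.attention_score_distribution)
                ),
                "topic": config.topics[int(rng.integers(len(config.topics)))],
            }
        )

    def _relation_for_topic(topic: str) -> str:
        if rng.random() < config.not_a_relation_rate:
            return NOT_A_RELATION
        tilt = (config.topic_tilt or {}).get(topic)
        if tilt:
            weights = np.array([tilt.get(lab, 1.0) for lab in non_null], dtype=float)
            weights /= weights.sum()
            return non_null[int(rng.choice(len(non_null), p=weights))]
        return non_null[int(rng.integers(len(non_null)))]

    records: list[RelationPrediction] = []
    for paper in papers:
        n_sent = int(rng.poisson(config.mean_sentences_per_paper))
        k = 0
        for _ in range(n_sent):
            hi, ti = rng.choice(len(entity_ids), size=2, replace=False)
            head_id, tail_id = entity_ids[int(hi)], entity_ids[int(ti)]
            relation = _relation_for_topic(paper["topic"])
            prob = _draw_probability(rng, config.probability_concentration)
            head_name, head_type = entities[head_id]
            tail_name, tail_type = entities[tail_id]
            records.append(
                RelationPrediction(
                    paper_id=paper["paper_id"],
                    sentence_id=f"{paper['paper_id']}:{k}",
                    sentence=_make_sentence(rng, head_name, relation, tail_name),
                    head_id=head_id,
                    head_name=head_name,
                    head_type=head_type,
                    tail_id=tail_id,
                    tail_name=tail_name,
                    tail_type=tail_type,
                    relation=relation,
                    probability=prob,
                    topic=paper["topic"],
                    date=paper["date"],
                    attention_score=paper["attention_score"],
                )
            )
            k += 1
            if (
                relation != NOT_A_RELATION
                and relation in inverse_map
                and rng.random() < config.inverse_pair_fraction
            ):
                records.append(
                    RelationPrediction(
                        paper_id=paper["paper_id"],
                        sentence_id=f"{paper['paper_id']}:{k}",
                        sentence=_make_sentence(
                            rng, tail_name, inverse_map.inverse(relation), head_name
                        ),
                        head_id=tail_id,
                        head_name=tail_name,
                        head_type=tail_type,
                        tail_id=head_id,
                        tail_name=head_name,
                        tail_type=head_type,
                        relation=inverse_map.inverse(relation),
                        probability=prob,
                        topic=paper["topic"],
                        date=paper["date"],
                        attention_score=paper["attention_score"],
                    )
                )
                k += 1

    emitted = {}
    for rec in records:
        emitted[rec.paper_id] = emitted.get(rec.paper_id, 0) + 1
    metadata = pd.DataFrame(papers)
    if not metadata.empty:
        metadata["n_sentences"] = [emitted.get(p, 0) for p in metadata["paper_id"]]
    else:
        metadata = pd.DataFrame(
            columns=["paper_id", "date", "attention_score", "topic", "n_sentences"]
        )

    return SyntheticBundle(
        predictions=tuple(records),
        semantic_table=semantic_table,
        entities=entities,
        planted=(),
        paper_metadata=metadata,
        labels=tuple(labels),
        inverse_map=inverse_map,
        class_map=class_map,
        provenance=(f"generated(seed={config.seed})",),
    )


def make_planted_patterns(
    pattern: str,
    n: int,
    target_id: str = DEFAULT_TARGET_ID,
    id_offset: int = 0,
) -> list[PlantedPattern]:
    """Fresh-node planted patterns (CUIs in the C8xxxxxx range avoid
    collisions with generated background entities)."""
    out = []
    for i in range(n):
        base = 3 * (id_offset + i)
        nodes = tuple(f"C8{base + j:06d}" for j in range(3)) + (target_id,)
        out.append(PlantedPattern(pattern=pattern, node_ids=nodes))
    return out


def _edge_records(
    head_id: str,
    tail_id: str,
    relation: str,
    entities: Mapping[str, tuple[str, str]],
    paper_rows: Sequence[Mapping],
    rng: np.random.Generator,
    concentration: float,
    sentence_counter: dict[str, int],
) -> list[RelationPrediction]:
    recs = []
    head_name, head_type = entities[head_id]
    tail_name, tail_type = entities[tail_id]
    for paper in paper_rows:
        k = sentence_counter[paper["paper_id"]] = sentence_counter.get(paper["paper_id"], 0) + 1
        recs.append(
            RelationPrediction(
                paper_id=paper["paper_id"],
                sentence_id=f"{paper['paper_id']}:planted:{k}",
                sentence=_make_sentence(rng, head_name, relation, tail_name),
                head_id=head_id,
                head_name=head_name,
                head_type=head_type,
                tail_id=tail_id,
                tail_name=tail_name,
                tail_type=tail_type,
                relation=relation,
                probability=_draw_probability(rng, concentration),
                topic=paper["topic"],
                date=paper["date"],
                attention_score=paper["attention_score"],
            )
        )
    return recs


def _planting_papers(
    rng: np.random.Generator, n: int, start_index: int, reference_date: date
) -> list[dict]:
    return [
        {
            "paper_id": f"PLANT{start_index + i:04d}",
            "date": reference_date.isoformat(),
            "attention_score": float(rng.lognormal(1.0, 1.0)),
            "topic": "treatment",
        }
        for i in range(n)
    ]


def plant_drug_paths(
    bundle: SyntheticBundle,
    patterns: Sequence[PlantedPattern],
    seed: int,
    n_evidence_papers: int = 2,
) -> SyntheticBundle:
    """Insert the required and qualification edges of each pattern into a bundle.

    Every planted edge is emitted from ``n_evidence_papers`` distinct
    provenance papers (default 2, so the "at least two different texts"
    condition holds for planted structure).  Missing nodes — including the
    target — are created with the pattern's node types.  A pattern whose
    drug already has a direct edge to the target raises
    :class:`PlantingConflictError`; ground truth is recorded in
    ``bundle.planted``.
    """
    if not patterns:
        return dataclasses.replace(
            bundle, provenance=bundle.provenance + ("plant(none)",)
        )
    rng = np.random.default_rng(seed)

    direct: set[frozenset] = set()
    for rec in bundle.predictions:
        direct.add(frozenset((rec.head_id, rec.tail_id)))
    for pat in patterns:
        if frozenset((pat.drug_id, pat.target_id)) in direct:
            raise PlantingConflictError(
                f"drug {pat.drug_id} already directly linked to target {pat.target_id}"
            )

    entities = dict(bundle.entities)
    semantic_table = dict(bundle.semantic_table)
    for pat in patterns:
        for node, etype in pat.node_types().items():
            if node not in entities:
                name = DEFAULT_TARGET_NAME if node == DEFAULT_TARGET_ID else f"{etype}_{node}"
                entities[node] = (name, etype)
                semantic_table[node] = _entity_semantic_record(node, etype)

    mid_date = bundle.paper_metadata["date"].iloc[0] if len(bundle.paper_metadata) else "2022-06-01"
    papers = _planting_papers(rng, n_evidence_papers, 0, date.fromisoformat(str(mid_date)))

    new_records: list[RelationPrediction] = []
    counter: dict[str, int] = {}
    concentration = 8.0  # planted evidence is high-confidence by design
    for pat in patterns:
        for head, cls, tail in pat.required_edges():
            new_records.extend(
                _edge_records(
                    head, tail, _CLASS_LABEL[cls], entities, papers, rng,
                    concentration, counter,
                )
            )

    extra_meta = pd.DataFrame(
        [
            {**p, "n_sentences": counter.get(p["paper_id"], 0)}
            for p in papers
        ]
    )
    metadata = pd.concat([bundle.paper_metadata, extra_meta], ignore_index=True)

    return dataclasses.replace(
        bundle,
        predictions=bundle.predictions + tuple(new_records),
        entities=entities,
        semantic_table=semantic_table,
        planted=bundle.planted + tuple(patterns),
        paper_metadata=metadata,
        provenance=bundle.provenance + (f"plant({len(patterns)} patterns, seed={seed})",),
    )


def inject_edge_records(
    bundle: SyntheticBundle,
    edges: Sequence[tuple[str, str, str]],
    seed: int,
    n_evidence_papers: int = 2,
    node_types: Mapping[str, str] | None = None,
) -> SyntheticBundle:
    """Insert arbitrary (head, relation, tail) edges as prediction records.

    Used to build decoy structures (e.g. paths deliberately missing a
    qualification edge) for negative-control experiments.  Unknown nodes are
    created with types from ``node_types`` (default "unknown").
    """
    rng = np.random.default_rng(seed)
    entities = dict(bundle.entities)
    semantic_table = dict(bundle.semantic_table)
    node_types = dict(node_types or {})
    for head, _, tail in edges:
        for node in (head, tail):
            if node not in entities:
                etype = node_types.get(node, "unknown")
                name = DEFAULT_TARGET_NAME if node == DEFAULT_TARGET_ID else f"{etype}_{node}"
                entities[node] = (name, etype)
                if etype in _TYPE_INFO:
                    semantic_table[node] = _entity_semantic_record(node, etype)
    papers = _planting_papers(rng, n_evidence_papers, 9000, date(2022, 6, 1))
    counter: dict[str, int] = {}
    new_records: list[RelationPrediction] = []
    for head, relation, tail in edges:
        new_records.extend(
            _edge_records(head, tail, relation, entities, papers, rng, 8.0, counter)
        )
    extra_meta = pd.DataFrame(
        [{**p, "n_sentences": counter.get(p["paper_id"], 0)} for p in papers]
    )
    return dataclasses.replace(
        bundle,
        predictions=bundle.predictions + tuple(new_records),
        entities=entities,
        semantic_table=semantic_table,
        paper_metadata=pd.concat([bundle.paper_metadata, extra_meta], ignore_index=True),
        provenance=bundle.provenance + (f"inject({len(edges)} edges, seed={seed})",),
    )
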