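"""Sentence-level predictions → unique aggregated relation triples.

Each sentence-level prediction asserts one (head, relation, tail) triple
with a confidence probability.  Aggregation merges identical triples across
the corpus after removing "not a relation" records and canonicalizing
inverse-direction label pairs (e.g. "may be treated by" rewritten to
"may treat" with swapped endpoints).  An aggregated triple keeps the number
of distinct source papers, the mean and the sum of the contributing
probabilities, and the source-paper set — the edge attributes of the
downstream knowledge graph.

Credibility filters restrict the record stream before aggregation:
a publication-date window, an above-mean attention-score (Altmetric-style)
cut, and a conclusive-language keyword rule.
"""

from __future__ import annotations

import csv
import json
import logging
import re
import warnings
from dataclasses import dataclass, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    InvalidInputError,
    ParseError,
    UnknownRelationError,
)
from .evaluate import NOT_A_RELATION

logger = logging.getLogger(__name__)

__all__ = [
    "RelationPrediction",
    "InversePairMap",
    "AggregatedTriple",
    "CredibilityRules",
    "DEFAULT_CONCLUSIVE_KEYWORDS",
    "drop_non_relations",
    "canonicalize_direction",
    "aggregate_triples",
    "aggregate_predictions",
    "filter_date_window",
    "filter_attention_above_mean",
    "filter_conclusive",
    "rank_drugs_by_prob_sum",
    "read_predictions_jsonl",
    "write_predictions_jsonl",
    "write_predictions_tsv",
    "read_predictions_tsv",
    "write_triples_tsv",
]

#: Default conclusive-language cue words for the abstract credibility rule.
DEFAULT_CONCLUSIVE_KEYWORDS = (
    "conclude",
    "demonstrate",
    "show",
    "confirm",
    "improve",
    "reduce",
    "effective",
    "efficacious",
)

_PREDICTION_FIELDS = (
    "paper_id",
    "sentence_id",
    "sentence",
    "head_id",
    "head_name",
    "head_type",
    "tail_id",
    "tail_name",
    "tail_type",
    "relation",
    "probability",
    "topic",
    "date",
    "attention_score",
)


def _coerce_date(value: "date | str") -> date:
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(value)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"unparsable date {value!r} (expected ISO YYYY-MM-DD)") from exc


@dataclass(frozen=True)
class RelationPrediction:
    """One sentence-level relation extraction with provenance."""

    paper_id: str
    sentence_id: str
    sentence: str
    head_id: str
    head_name: str
    head_type: str
    tail_id: str
    tail_name: str
    tail_type: str
    relation: str
    probability: float
    topic: str
    date: date
    attention_score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "date", _coerce_date(self.date))
        if not (0.0 < self.probability <= 1.0):
            raise InvalidInputError(
                f"probability must lie in (0, 1], got {self.probability}"
            )
        if self.head_id == self.tail_id:
            raise InvalidInputError(f"head and tail entity coincide: {self.head_id}")
        if self.attention_score < 0:
            raise InvalidInputError("attention_score must be nonnegative")

    def to_dict(self) -> dict:
        row = {f: getattr(self, f) for f in _PREDICTION_FIELDS}
        row["date"] = self.date.isoformat()
        return row

    @classmethod
    def from_dict(cls, row: Mapping) -> "RelationPrediction":
        kwargs = {f: row[f] for f in _PREDICTION_FIELDS}
        kwargs["probability"] = float(kwargs["probability"])
        kwargs["attention_score"] = float(kwargs["attention_score"])
        return cls(**kwargs)


class InversePairMap:
    """Involution over relation labels pairing each label with its inverse.

    Exactly one label of each non-symmetric pair is flagged canonical;
    symmetric labels (their own inverse) are always canonical.
    """

    def __init__(self, mapping: Mapping[str, tuple[str, bool]]):
        for label, (inv, canonical) in mapping.items():
            if inv not in mapping:
                raise ConfigurationError(f"inverse {inv!r} of {label!r} missing from map")
            back, inv_canonical = mapping[inv]
            if back != label:
                raise ConfigurationError(
                    f"involution violated: inverse({inv!r}) = {back!r}, expected {label!r}"
                )
            if inv == label:
                if not canonical:
                    raise ConfigurationError(f"symmetric label {label!r} must be canonical")
            elif canonical == inv_canonical:
                raise ConfigurationError(
                    f"exactly one of ({label!r}, {inv!r}) must be canonical"
                )
        self._map = dict(mapping)

    def __contains__(self, label: str) -> bool:
        return label in self._map

    def __len__(self) -> int:
        return len(self._map)

    def inverse(self, label: str) -> str:
        return self._map[label][0]

    def is_canonical(self, label: str) -> bool:
        return self._map[label][1]

    def labels(self) -> list[str]:
        return list(self._map)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        symmetric: Iterable[str] = (),
    ) -> "InversePairMap":
        """Build from (canonical, inverse) pairs plus self-inverse labels."""
        mapping: dict[str, tuple[str, bool]] = {}
        for canonical, inverse in pairs:
            mapping[canonical] = (inverse, True)
            mapping[inverse] = (canonical, False)
        for label in symmetric:
            mapping[label] = (label, True)
        return cls(mapping)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "pairs": sorted(
                [lab, self.inverse(lab)]
                for lab in self._map
                if self.is_canonical(lab) and self.inverse(lab) != lab
            ),
            "symmetric": sorted(lab for lab in self._map if self.inverse(lab) == lab),
        }
        Path(path).write_text(yaml.safe_dump(payload), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InversePairMap":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_pairs(
            [tuple(p) for p in payload.get("pairs", [])],
            payload.get("symmetric", []),
        )


@dataclass(frozen=True)
class AggregatedTriple:
    """A unique (head, relation, tail) edge with corpus-level provenance."""

    head_id: str
    relation: str
    tail_id: str
    direction: str  # "forward" | "inverse-collapsed"
    n_sources: int
    prob_mean: float
    prob_sum: float
    source_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_sources != len(self.source_ids) or self.n_sources < 1:
            raise InvalidInputError("n_sources must equal |source_ids| >= 1")


@dataclass(frozen=True)
class CredibilityRules:
    """The three credibility-preprocessing rules for treatment triples."""

    date_window: tuple[date, date] = (date(2022, 6, 1), date(2023, 6, 1))
    attention_above_mean: bool = True
    conclusive_keywords: tuple[str, ...] = DEFAULT_CONCLUSIVE_KEYWORDS

    def __post_init__(self) -> None:
        start, end = (_coerce_date(d) for d in self.date_window)
        object.__setattr__(self, "date_window", (start, end))
        if start > end:
            raise ConfigurationError(f"date window start {start} after end {end}")
        if not self.conclusive_keywords:
            raise ConfigurationError("conclusive keyword set must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CredibilityRules":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            date_window=tuple(payload["date_window"]),
            attention_above_mean=bool(payload.get("attention_above_mean", True)),
            conclusive_keywords=tuple(payload["conclusive_keywords"]),
        )


def drop_non_relations(
    records: Sequence[RelationPrediction], null_label: str = NOT_A_RELATION
) -> list[RelationPrediction]:
    """Remove records labeled with the null relation, preserving order."""
    return [r for r in records if r.relation != null_label]


def canonicalize_direction(
    record: RelationPrediction, pair_map: InversePairMap, strict: bool = False
) -> RelationPrediction:
    """Rewrite a non-canonical relation to its canonical label, swapping endpoints.

    Canonical (and, in lenient mode, unknown) relations return the input
    object unchanged, so identity can be tested with ``is``.
    """
    if record.relation not in pair_map:
        if strict:
            raise UnknownRelationError(record.relation)
        return record
    if pair_map.is_canonical(record.relation):
        return record
    return replace(
        record,
        relation=pair_map.inverse(record.relation),
        head_id=record.tail_id,
        head_name=record.tail_name,
        head_type=record.tail_type,
        tail_id=record.head_id,
        tail_name=record.head_name,
        tail_type=record.head_type,
    )


def aggregate_triples(
    records: Sequence[RelationPrediction],
    flipped_keys: frozenset[tuple[str, str, str]] | None = None,
) -> list[AggregatedTriple]:
    """Merge identical (head, relation, tail) triples.

    ``n_sources`` counts distinct source papers (not sentences); the mean and
    sum of probabilities run over all contributing records.  ``flipped_keys``
    marks triple keys that received at least one direction-collapsed record
    (set by :func:`aggregate_predictions`).
    """
    flipped_keys = flipped_keys or frozenset()
    groups: dict[tuple[str, str, str], list[RelationPrediction]] = {}
    for rec in records:
        groups.setdefault((rec.head_id, rec.relation, rec.tail_id), []).append(rec)
    triples = []
    for key in sorted(groups):
        members = groups[key]
        probs = [m.probability for m in members]
        sources = frozenset(m.paper_id for m in members)
        triples.append(
            AggregatedTriple(
                head_id=key[0],
                relation=key[1],
                tail_id=key[2],
                direction="inverse-collapsed" if key in flipped_keys else "forward",
                n_sources=len(sources),
                prob_mean=sum(probs) / len(probs),
                prob_sum=sum(probs),
                source_ids=sources,
            )
        )
    return triples


def aggregate_predictions(
    records: Sequence[RelationPrediction],
    pair_map: InversePairMap | None = None,
    null_label: str = NOT_A_RELATION,
    collapse_inverse: bool = True,
    strict: bool = False,
) -> list[AggregatedTriple]:
    """Full merge pipeline: drop nulls, canonicalize directions, aggregate."""
    kept = drop_non_relations(records, null_label)
    flipped: set[tuple[str, str, str]] = set()
    if collapse_inverse and pair_map is not None:
        canon = []
        for rec in kept:
            c = canonicalize_direction(rec, pair_map, strict=strict)
            if c is not rec:
                flipped.add((c.head_id, c.relation, c.tail_id))
            canon.append(c)
        kept = canon
    return aggregate_triples(kept, frozenset(flipped))


def filter_date_window(
    records: Sequence[RelationPrediction], window: tuple["date | str", "date | str"]
) -> list[RelationPrediction]:
    """Keep records whose publication date lies in the inclusive window."""
    start, end = (_coerce_date(d) for d in window)
    if start > end:
        raise ConfigurationError(f"date window start {start} after end {end}")
    return [r for r in records if start <= r.date <= end]


def filter_attention_above_mean(
    records: Sequence[RelationPrediction],
    paper_scores: "Mapping[str, float] | pd.DataFrame",
) -> list[RelationPrediction]:
    """Keep records from papers whose attention score strictly exceeds the mean.

    The mean runs over all papers in the score table.  Papers missing from
    the table score 0 (logged), mirroring how unindexed articles behave in
    attention databases.
    """
    if isinstance(paper_scores, pd.DataFrame):
        scores = dict(zip(paper_scores["paper_id"], paper_scores["attention_score"]))
    else:
        scores = dict(paper_scores)
    if not scores:
        raise InvalidInputError("attention score table is empty")
    mean = sum(scores.values()) / len(scores)
    missing = {r.paper_id for r in records} - scores.keys()
    if missing:
        logger.warning(
            "%d papers missing from attention table, treated as score 0", len(missing)
        )
    return [r for r in records if scores.get(r.paper_id, 0.0) > mean]


def filter_conclusive(
    records: Sequence[RelationPrediction], rules: CredibilityRules
) -> list[RelationPrediction]:
    """Keep records whose sentence contains a conclusive keyword.

    Matching is case-insensitive on word-boundary stems, so "demonstrate"
    also matches "demonstrated" but "effective" does not match
    "cost-ineffectiveness".
    """
    pattern = re.compile(
        r"\b(?:" + "|".join(re.escape(k) for k in rules.conclusive_keywords) + r")",
        flags=re.IGNORECASE,
    )
    return [r for r in records if pattern.search(r.sentence)]


def rank_drugs_by_prob_sum(
    triples: Sequence[AggregatedTriple],
    treatment_relations: Iterable[str],
    target_id: str,
) -> pd.DataFrame:
    """Rank drugs with a treatment-class triple to the target by Σ prob_sum.

    Returns a DataFrame (drug_id, score, n_triples) sorted by descending
    score, ties broken lexicographically by drug ID.
    """
    treatment = set(treatment_relations)
    hits = [
        t for t in triples if t.relation in treatment and t.tail_id == target_id
    ]
    if not any(t.head_id == target_id or t.tail_id == target_id for t in triples):
        warnings.warn(f"target {target_id!r} absent from triple set", stacklevel=2)
    rows: dict[str, dict] = {}
    for t in hits:
        row = rows.setdefault(t.head_id, {"drug_id": t.head_id, "score": 0.0, "n_triples": 0})
        row["score"] += t.prob_sum
        row["n_triples"] += 1
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (-r["score"], r["drug_id"])))
    if df.empty:
        df = pd.DataFrame(columns=["drug_id", "score", "n_triples"])
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O: predictions as JSONL / TSV, triples as TSV


def write_predictions_jsonl(records: Iterable[RelationPrediction], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), ensure_ascii=False) + "\n")


def read_predictions_jsonl(path: str | Path) -> list[RelationPrediction]:
    records = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(RelationPrediction.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_predictions_tsv(records: Iterable[RelationPrediction], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_PREDICTION_FIELDS, delimiter="\t",
                                lineterminator="\n")
        writer.writeheader()
        for rec in records:
            writer.writerow(rec.to_dict())


def read_predictions_tsv(path: str | Path) -> list[RelationPrediction]:
    records = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                records.append(RelationPrediction.from_dict(row))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_triples_tsv(triples: Iterable[AggregatedTriple], path: str | Path) -> None:
    """Aggregated triples as TSV; source paper IDs semicolon-joined."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["head_id", "relation", "tail_id", "direction", "n_sources",
             "prob_mean", "prob_sum", "source_ids"]
        )
        for t in triples:
            writer.writerow(
                [t.head_id, t.relation, t.tail_id, t.direction, t.n_sources,
                 repr(t.prob_mean), repr(t.prob_sum), ";".join(sorted(t.source_ids))]
            )
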