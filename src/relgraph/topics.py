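"""Relation-type enrichment, correlation, PCA and entity-type strength by topic.

Articles carry one of eight curated topic labels (general information,
mechanism, transmission, diagnosis, treatment, prevention, case report,
epidemic forecasting).  Per topic we count relation labels over the
article's extracted predictions and normalize to proportions.  Two
pairwise topic-similarity views are computed: *amount* (Pearson correlation
of proportion vectors over the union label set) and *diversity* (Jaccard
index of the relation-presence sets).  A 2-component PCA of the proportion
vectors places topics in the plane; entity-type strength tabulates, per
unordered entity-type pair, the number of relation records and the number
of distinct relation types.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .aggregate import InversePairMap, RelationPrediction
from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "TopicProfile",
    "TopicCorrelationMatrix",
    "PCAEmbedding",
    "EntityTypeStrength",
    "build_topic_profiles",
    "top_k_relations",
    "topic_correlation",
    "pca_topics",
    "entity_type_strength",
]


@dataclass(frozen=True)
class TopicProfile:
    """Relation-label counts and proportions for one article topic."""

    topic: str
    counts: Mapping[str, int]
    proportions: Mapping[str, float]
    papers_used: frozenset[str]

    @property
    def n_records(self) -> int:
        return sum(self.counts.values())


def build_topic_profiles(
    records: Sequence[RelationPrediction],
    equalize: bool = False,
    seed: int = 0,
) -> list[TopicProfile]:
    """One relation-count profile per topic present in the records.

    With ``equalize`` set, every topic is subsampled (seeded, without
    replacement) to the minimum per-topic distinct-paper count before
    counting, emulating an equal-articles-per-topic corpus design.
    A topic with zero papers cannot be equalized and raises
    :class:`InvalidInputError`.
    """
    if not records:
        raise InvalidInputError("no records to profile")
    by_topic: dict[str, list[RelationPrediction]] = {}
    for rec in records:
        by_topic.setdefault(rec.topic, []).append(rec)

    papers_by_topic = {
        topic: sorted({r.paper_id for r in recs}) for topic, recs in by_topic.items()
    }
    if equalize:
        empty = [t for t, papers in papers_by_topic.items() if not papers]
        if empty:
            raise InvalidInputError(f"cannot equalize topics with zero papers: {empty}")
        m = min(len(p) for p in papers_by_topic.values())
        rng = np.random.default_rng(seed)
        keep = {
            topic: frozenset(rng.choice(papers, size=m, replace=False))
            for topic, papers in papers_by_topic.items()
        }
    else:
        keep = {topic: frozenset(papers) for topic, papers in papers_by_topic.items()}

    profiles = []
    for topic in sorted(by_topic):
        kept = [r for r in by_topic[topic] if r.paper_id in keep[topic]]
        counts: dict[str, int] = {}
        for rec in kept:
            counts[rec.relation] = counts.get(rec.relation, 0) + 1
        total = sum(counts.values())
        proportions = {k: v / total for k, v in counts.items()} if total else {}
        profiles.append(
            TopicProfile(
                topic=topic,
                counts=counts,
                proportions=proportions,
                papers_used=keep[topic],
            )
        )
    return profiles


def top_k_relations(profile: TopicProfile, k: int = 10) -> list[str]:
    """The k highest-proportion relation labels; ties resolve lexicographically."""
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    ordered = sorted(profile.proportions.items(), key=lambda kv: (-kv[1], kv[0]))
    return [label for label, _ in ordered[:k]]


@dataclass(frozen=True)
class TopicCorrelationMatrix:
    """Symmetric topic × topic similarity matrix for one mode."""

    mode: str  # "amount" | "diversity"
    matrix: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.matrix.to_csv(path)


def _proportion_vectors(profiles: Sequence[TopicProfile]) -> pd.DataFrame:
    labels = sorted({lab for p in profiles for lab in p.proportions})
    return pd.DataFrame(
        [[p.proportions.get(lab, 0.0) for lab in labels] for p in profiles],
        index=[p.topic for p in profiles],
        columns=labels,
    )


def topic_correlation(
    profiles: Sequence[TopicProfile], mode: str = "amount"
) -> TopicCorrelationMatrix:
    """Pairwise topic similarity.

    ``amount``: Pearson correlation of proportion vectors over the union
    label set (absent labels count 0); a constant vector yields NaN
    off-diagonal entries (undefined, reported as missing).  ``diversity``:
    Jaccard index of relation-presence sets.
    """
    if len(profiles) < 2:
        raise InvalidInputError("need at least two topic profiles")
    topics = [p.topic for p in profiles]
    n = len(profiles)
    out = np.full((n, n), np.nan)
    if mode == "amount":
        vectors = _proportion_vectors(profiles).to_numpy()
        stds = vectors.std(axis=1)
        for i in range(n):
            out[i, i] = 1.0
            for j in range(i + 1, n):
                if stds[i] == 0 or stds[j] == 0:
                    continue  # undefined: left as NaN
                out[i, j] = out[j, i] = float(np.corrcoef(vectors[i], vectors[j])[0, 1])
    elif mode == "diversity":
        present = [frozenset(lab for lab, c in p.counts.items() if c > 0) for p in profiles]
        for i in range(n):
            for j in range(i, n):
                union = present[i] | present[j]
                val = len(present[i] & present[j]) / len(union) if union else 0.0
                out[i, j] = out[j, i] = val
    else:
        raise InvalidInputError(f"unknown mode {mode!r}; expected 'amount' or 'diversity'")
    return TopicCorrelationMatrix(mode=mode, matrix=pd.DataFrame(out, index=topics, columns=topics))


@dataclass(frozen=True)
class PCAEmbedding:
    """Topic coordinates on the first two principal axes."""

    coordinates: Mapping[str, tuple[float, float]]
    explained_variance_ratio: tuple[float, ...]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(t, x, y) for t, (x, y) in self.coordinates.items()],
            columns=["topic", "pc1", "pc2"],
        ).to_csv(path, index=False)


def pca_topics(
    profiles: Sequence[TopicProfile], standardize: bool = False
) -> PCAEmbedding:
    """Project topic proportion vectors onto the top-2 principal axes.

    Vectors are centered (optionally standardized); the sign of each
    component is fixed by making its largest-magnitude loading positive
    (first index wins ties), so embeddings are reproducible across runs.
    """
    if len(profiles) < 2:
        raise DegenerateInputError("need at least two topic profiles")
    table = _proportion_vectors(profiles)
    if len(set(map(tuple, table.to_numpy().tolist()))) < 2:
        raise DegenerateInputError("need at least two distinct topic profiles")
    X = table.to_numpy()
    if standardize:
        std = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(std == 0, 1.0, std)
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    components = pca.components_.copy()
    for j in range(n_comp):
        i = int(np.argmax(np.abs(components[j])))
        if components[j, i] < 0:
            components[j] *= -1
            coords[:, j] *= -1
    if n_comp < 2:  # pad the degenerate second axis with zeros
        coords = np.hstack([coords, np.zeros((coords.shape[0], 2 - n_comp))])
    evr = tuple(float(v) for v in pca.explained_variance_ratio_)
    return PCAEmbedding(
        coordinates={
            t: (float(x), float(y)) for t, (x, y) in zip(table.index, coords[:, :2])
        },
        explained_variance_ratio=evr,
    )


@dataclass(frozen=True)
class EntityTypeStrength:
    """Entity-type × entity-type relation-strength matrices.

    ``n_relations`` counts records per unordered type pair; ``n_relation_types``
    counts distinct relation labels per pair (inverse pairs collapsed when an
    inverse-pair map is supplied).
    """

    n_relations: pd.DataFrame
    n_relation_types: pd.DataFrame


def entity_type_strength(
    records: Sequence[RelationPrediction],
    pair_map: InversePairMap | None = None,
) -> EntityTypeStrength:
    """Tabulate relation volume and diversity for every entity-type pair."""
    types = sorted({r.head_type for r in records} | {r.tail_type for r in records})
    counts: dict[tuple[str, str], int] = {}
    labelsets: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        key = tuple(sorted((rec.head_type, rec.tail_type)))
        label = rec.relation
        if pair_map is not None and label in pair_map and not pair_map.is_canonical(label):
            label = pair_map.inverse(label)
        counts[key] = counts.get(key, 0) + 1
        labelsets.setdefault(key, set()).add(label)
    n_rel = pd.DataFrame(0, index=types, columns=types, dtype=int)
    n_typ = pd.DataFrame(0, index=types, columns=types, dtype=int)
    for (a, b), c in counts.items():
        n_rel.loc[a, b] = n_rel.loc[b, a] = c
        k = len(labelsets[(a, b)])
        n_typ.loc[a, b] = n_typ.loc[b, a] = k
    return EntityTypeStrength(n_relations=n_rel, n_relation_types=n_typ)
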